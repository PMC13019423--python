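"""Sample-size adequacy by resampling: stability of classification
performance versus per-group n, and permutation-based empirical power.

The source of replicates is either a generator configuration (fresh
synthetic draws per replicate — unbiased) or an existing SpectraSet
(subsampling without replacement).  Each replicate runs the same
preprocess → PLS-DA LOO-CV path as the main analysis; power is the
fraction of replicates whose permutation test rejects at level alpha.

Power loops search fewer PLS components (default 5) than the one-shot
analysis; on these data the LOO-selected component count sits well below
that, and the reduced search keeps the permutation loops desk-scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpectraSet
from .plsda import loo_cv, permutation_test
from .preprocess import preprocess_pipeline
from .synthetic import GeneratorConfig, generate_dataset

__all__ = [
    "PowerCurve",
    "stability_curve",
    "empirical_power",
    "power_report",
    "stabilization_n",
]

_SEED_MOD = 2**31 - 1


@dataclass
class PowerCurve:
    n_grid: list
    mean_accuracy: list
    sd_accuracy: list
    power: list
    alpha: float
    reps: int
    n_perm: int
    seed: int


def _replicate(source, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One replicate's preprocessed matrix and labels (n per group)."""
    if isinstance(source, GeneratorConfig):
        cfg_dict = {k: v for k, v in vars(source).items() if k not in ("seed", "n_per_group")}
        cfg = GeneratorConfig(seed=seed, n_per_group=n, **cfg_dict)
        spectra, _ = generate_dataset(cfg)
    elif isinstance(source, SpectraSet):
        rng = np.random.default_rng(seed)
        keep = []
        labels = source.labels
        for g in source.groups:
            idx = np.flatnonzero(labels == g)
            if idx.size < n:
                raise ValueError(
                    f"group {g!r} has {idx.size} spectra; cannot subsample {n} without replacement"
                )
            keep.extend(rng.choice(idx, size=n, replace=False))
        spectra = source.subset(np.sort(np.array(keep)))
    else:
        raise TypeError("source must be a GeneratorConfig or a SpectraSet")
    pre = preprocess_pipeline(spectra)
    return pre.intensities, pre.labels


def stability_curve(
    source, n_grid=(10, 20, 30, 40), reps: int = 50, seed: int = 0, a_max: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sd of LOO accuracy at each per-group sample size."""
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for n in n_grid:
        acc = np.empty(reps)
        for r in range(reps):
            X, labels = _replicate(source, int(n), int(rng.integers(_SEED_MOD)))
            _, acc[r], _, _, _ = loo_cv(X, labels, a_max)
        means.append(float(acc.mean()))
        sds.append(float(acc.std(ddof=1)) if reps > 1 else 0.0)
    return np.array(means), np.array(sds)


def stabilization_n(n_grid, mean_accuracy, tol: float = 0.02) -> int:
    """Smallest n whose mean accuracy is within ``tol`` of the largest-n mean."""
    n_grid = list(n_grid)
    ref = mean_accuracy[int(np.argmax(n_grid))]
    for n, m in sorted(zip(n_grid, mean_accuracy)):
        if abs(m - ref) <= tol:
            return int(n)
    return int(max(n_grid))


def empirical_power(
    source,
    n: int,
    alpha: float = 0.05,
    reps: int = 50,
    n_perm: int = 199,
    seed: int = 0,
    a_max: int = 5,
) -> float:
    """Fraction of replicates whose permutation test rejects at ``alpha``."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if reps < 20:
        raise ValueError("reps must be >= 20")
    rng = np.random.default_rng(seed)
    rejections = 0
    for r in range(reps):
        X, labels = _replicate(source, int(n), int(rng.integers(_SEED_MOD)))
        p, _, _ = permutation_test(
            X, labels, n_perm=n_perm, seed=int(rng.integers(_SEED_MOD)), a_max=a_max
        )
        rejections += p < alpha
    return rejections / reps


def full_power_curve(
    source, n_grid=(10, 20, 30, 40), alpha: float = 0.05, reps: int = 50,
    n_perm: int = 199, seed: int = 0, a_max: int = 5,
) -> PowerCurve:
    """Stability and power on one grid (convenience wrapper)."""
    means, sds = stability_curve(source, n_grid, reps, seed, a_max)
    powers = [
        empirical_power(source, int(n), alpha, reps, n_perm, seed + 1 + i, a_max)
        for i, n in enumerate(n_grid)
    ]
    return PowerCurve(list(n_grid), list(means), list(sds), powers, alpha, reps, n_perm, seed)


def power_report(curve: PowerCurve, csv_path, json_path=None) -> None:
    """CSV of the curve plus JSON metadata; deterministic output."""
    df = pd.DataFrame(
        {
            "n": curve.n_grid,
            "mean_accuracy": curve.mean_accuracy,
            "sd_accuracy": curve.sd_accuracy,
            "power": curve.power,
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {k: v for k, v in asdict(curve).items()
            if k in ("alpha", "reps", "n_perm", "seed")}
    if json_path is None:
        json_path = Path(csv_path).with_suffix(".json")
    Path(json_path).write_text(json.dumps(meta, indent=2), encoding="utf-8")
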