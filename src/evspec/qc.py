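"""PCA-model-based sample QC: reduced Hotelling T² and reduced Q residuals.

Quality control runs on mean-centered raw spectra.  A PCA model retains
enough components to explain a target share of variance; each sample then
gets two diagnostics: Hotelling's T² (Mahalanobis distance of its scores
from the model centre — a score outlier statistic) and the Q residual
(squared distance to its projection on the retained components — an
off-model outlier statistic).  Both are divided by their 95% confidence
limits, so values above 1 flag outliers, matching the "reduced" T²-vs-Q
graph convention.

The T² limit uses the F-distribution relation
``A(n-1)/(n-A) · F_{1-α}(A, n-A)``; the Q limit uses the
Jackson–Mudholkar approximation built from the discarded eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectraSet
from .preprocess import mean_center

__all__ = [
    "PCAModel",
    "OutlierReport",
    "fit_pca",
    "hotelling_t2_reduced",
    "q_residuals_reduced",
    "flag_outliers",
    "run_qc",
    "choose_n_components",
]


@dataclass
class PCAModel:
    """PCA of a mean-centered matrix via SVD.

    ``loadings`` (p×A) are orthonormal right singular directions with the
    sign fixed so each column's largest-magnitude entry is positive;
    ``eigenvalues`` are the score variances (divisor n−1).
    ``residual_eigenvalues`` holds the discarded spectrum, needed for the
    Q-residual confidence limit.
    """

    mean: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    residual_eigenvalues: np.ndarray
    n_samples: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.loadings


def fit_pca(matrix: np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA with ``n_components`` retained directions."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    Xc, mean = mean_center(X)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig_all = s**2 / (n - 1)
    load = Vt[:n_components].T
    flip = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    load = load * flip
    scores = Xc @ load
    total = eig_all.sum()
    evr = eig_all[:n_components] / total if total > 0 else np.zeros(n_components)
    return PCAModel(
        mean=mean,
        loadings=load,
        eigenvalues=eig_all[:n_components],
        scores=scores,
        explained_variance_ratio=evr,
        residual_eigenvalues=eig_all[n_components:],
        n_samples=n,
    )


def choose_n_components(
    matrix: np.ndarray, var_explained: float = 0.90, cap: int = 10
) -> int:
    """Smallest A explaining at least ``var_explained`` of variance, capped."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = X.shape
    Xc, _ = mean_center(X)
    s = np.linalg.svd(Xc, compute_uv=False)
    eig = s**2
    frac = np.cumsum(eig) / eig.sum()
    A = int(np.searchsorted(frac, var_explained) + 1)
    return max(1, min(A, cap, n - 1, p))


def t2_limit(model: PCAModel, conf: float = 0.95) -> float:
    """Hotelling T² limit: A(n−1)/(n−A) · F_{conf}(A, n−A)."""
    A, n = model.n_components, model.n_samples
    if n <= A:
        raise ValueError("need n > A for the T² limit")
    return A * (n - 1) / (n - A) * stats.f.ppf(conf, A, n - A)


def q_limit(model: PCAModel, conf: float = 0.95) -> float:
    """Jackson–Mudholkar Q-residual limit from the discarded eigenvalues."""
    lam = model.residual_eigenvalues
    lam = lam[lam > 0]
    if lam.size == 0:
        return 0.0
    th1, th2, th3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    z = stats.norm.ppf(conf)
    if h0 <= 0:
        # Degenerate residual spectrum; fall back to the log-normal form.
        return float(th1 * np.exp(z * np.sqrt(th2) / th1))
    term = z * np.sqrt(2.0 * th2 * h0**2) / th1 + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2
    return float(th1 * max(term, 0.0) ** (1.0 / h0))


def hotelling_t2_reduced(
    model: PCAModel, data: np.ndarray, conf: float = 0.95
) -> np.ndarray:
    """Per-sample T² divided by its confidence limit (>1 flags a score outlier)."""
    if np.any(model.eigenvalues <= 0):
        raise ValueError("zero eigenvalue among retained components")
    scores = model.transform(data)
    t2 = np.sum(scores**2 / model.eigenvalues, axis=1)
    return t2 / t2_limit(model, conf)


def q_residuals_reduced(
    model: PCAModel, data: np.ndarray, conf: float = 0.95
) -> np.ndarray:
    """Per-sample Q residual divided by its limit (>1 flags a residual outlier)."""
    Xc = np.atleast_2d(data) - model.mean
    resid = Xc - (Xc @ model.loadings) @ model.loadings.T
    q = np.sum(resid**2, axis=1)
    lim = q_limit(model, conf)
    if lim == 0.0:
        return np.zeros_like(q)
    return q / lim


@dataclass
class OutlierReport:
    """Per-sample reduced statistics and flags — the T²-vs-Q graph as a table."""

    sample_ids: np.ndarray
    t2_reduced: np.ndarray
    q_reduced: np.ndarray
    flagged: np.ndarray
    n_components: int
    conf: float = 0.95
    rule: str = "union"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "t2_reduced": self.t2_reduced,
                "q_reduced": self.q_reduced,
                "flagged": self.flagged,
            }
        )


def flag_outliers(
    t2_reduced: np.ndarray,
    q_reduced: np.ndarray,
    sample_ids=None,
    rule: str = "union",
    n_components: int = 0,
    conf: float = 0.95,
) -> OutlierReport:
    """Flag samples whose reduced T² or reduced Q exceeds 1.

    ``rule="union"`` flags if either statistic exceeds 1 (the default);
    ``"intersection"`` requires both.
    """
    t2 = np.asarray(t2_reduced, dtype=float)
    q = np.asarray(q_reduced, dtype=float)
    if t2.shape != q.shape:
        raise ValueError("t2_reduced and q_reduced must have equal length")
    if rule == "union":
        flagged = (t2 > 1) | (q > 1)
    elif rule == "intersection":
        flagged = (t2 > 1) & (q > 1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if sample_ids is None:
        sample_ids = np.arange(t2.size)
    return OutlierReport(
        np.asarray(sample_ids, dtype=object), t2, q, flagged, n_components, conf, rule
    )


def run_qc(
    spectra: SpectraSet,
    var_explained: float = 0.90,
    conf: float = 0.95,
    rule: str = "union",
    cap: int = 10,
) -> tuple[OutlierReport, SpectraSet]:
    """QC on raw spectra: PCA on the mean-centered matrix, T²/Q flags,
    and the surviving subset."""
    A = choose_n_components(spectra.intensities, var_explained, cap)
    model = fit_pca(spectra.intensities, A)
    t2 = hotelling_t2_reduced(model, spectra.intensities, conf)
    q = q_residuals_reduced(model, spectra.intensities, conf)
    report = flag_outliers(t2, q, spectra.sample_ids, rule, A, conf)
    survivors = spectra.subset(~report.flagged)
    survivors.provenance["qc"] = {
        "n_components": A,
        "conf": conf,
        "rule": rule,
        "n_flagged": int(report.flagged.sum()),
    }
    return report, survivors
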