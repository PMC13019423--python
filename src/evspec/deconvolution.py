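"""Albumin-corona removal by pseudo-Voigt reference deconvolution.

The albumin reference spectrum is fitted as a sum of pseudo-Voigt bands;
the fitted band shapes (centres, widths, mixing) are then held fixed and
scaled into each EV spectrum by nonnegative least squares; subtracting
the scaled sum leaves an estimate of the pure EV spectrum.  Per-band
scaling is the default — the corona's conformational environment shifts
band ratios, so a single global scale would force all-or-nothing removal
— but a global single-multiplier mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .bands import PseudoVoigtBand, WavenumberAxis, pseudo_voigt, sum_bands
from .spectra_io import BandTable

__all__ = [
    "PeakFit",
    "DeconvolutionResult",
    "fit_peak_sum",
    "project_reference",
    "deconvolute",
    "assign_peaks",
    "pick_initial_bands",
]


@dataclass
class PeakFit:
    bands: list
    residual_rms: float
    n_evaluations: int
    converged: bool


def _unpack(theta: np.ndarray, n_bands: int, assignments) -> list:
    out = []
    for i in range(n_bands):
        c, f, e, a = theta[4 * i: 4 * i + 4]
        out.append(PseudoVoigtBand(c, max(f, 1e-6), min(max(e, 0.0), 1.0), max(a, 0.0),
                                   assignments[i]))
    return out


def fit_peak_sum(
    axis: WavenumberAxis,
    spectrum: np.ndarray,
    initial_bands: list,
    center_window: float = 10.0,
    max_nfev: int = 20000,
) -> PeakFit:
    """Nonlinear least-squares fit of a pseudo-Voigt sum to a spectrum.

    Centres are bounded to ±``center_window`` cm⁻¹ of their initial
    positions, widths to [2, 200] cm⁻¹, eta to [0, 1] and amplitudes to
    nonnegative values.  The trust-region solver never increases the cost
    relative to the initial parameters.  On solver failure a second start
    (slightly perturbed) is tried; if that also fails a ``RuntimeError``
    carrying the best fit so far (``.best_fit``) is raised.
    """
    if not initial_bands:
        raise ValueError("initial_bands must be nonempty")
    y = np.asarray(spectrum, dtype=float)
    x = axis.values
    nb = len(initial_bands)
    assignments = [b.assignment for b in initial_bands]

    theta0, lo, hi = [], [], []
    for b in initial_bands:
        theta0 += [b.center, b.fwhm, b.eta, b.amplitude]
        lo += [b.center - center_window, 2.0, 0.0, 0.0]
        hi += [b.center + center_window, 200.0, 1.0, np.inf]
    theta0 = np.clip(theta0, lo, hi)

    def residual(theta):
        model = np.zeros_like(x)
        for i in range(nb):
            c, f, e, a = theta[4 * i: 4 * i + 4]
            model += pseudo_voigt(x, PseudoVoigtBand(c, f, e, a))
        return model - y

    best = None
    nfev = 0
    for attempt in range(2):
        start = theta0 if attempt == 0 else theta0 * (1 + 1e-3) + 1e-6
        start = np.clip(start, lo, hi)
        res = optimize.least_squares(
            residual, start, bounds=(lo, hi), method="trf", max_nfev=max_nfev
        )
        nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res
        if res.status > 0:
            bands = _unpack(res.x, nb, assignments)
            rms = float(np.sqrt(np.mean(res.fun**2)))
            return PeakFit(bands, rms, nfev, True)
    err = RuntimeError("peak-sum fit did not converge after restart")
    err.best_fit = PeakFit(  # type: ignore[attr-defined]
        _unpack(best.x, nb, assignments), float(np.sqrt(np.mean(best.fun**2))), nfev, False
    )
    raise err


def pick_initial_bands(
    axis: WavenumberAxis, spectrum: np.ndarray, prominence_frac: float = 0.05,
    default_fwhm: float = 30.0,
) -> list:
    """Initial bands from local maxima above a relative prominence threshold."""
    y = np.asarray(spectrum, dtype=float)
    prom = prominence_frac * (y.max() - y.min())
    idx, props = signal.find_peaks(y, prominence=prom)
    if idx.size == 0:
        idx = np.array([int(np.argmax(y))])
    bands = []
    for j in idx:
        bands.append(PseudoVoigtBand(float(axis.values[j]), default_fwhm, 0.5,
                                     max(float(y[j]), 0.0)))
    return bands


def project_reference(
    axis: WavenumberAxis,
    sample_spectrum: np.ndarray,
    reference_fit: PeakFit,
    scale_mode: str = "per-band",
    ev_basis: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale the fitted reference bands into a sample by NNLS.

    Band centres/widths/mixing stay fixed; only nonnegative amplitude
    multipliers are solved for — one per band (``per-band``) or a single
    common one (``global``).  Returns ``(scale_amplitudes, contribution)``.

    When ``ev_basis`` bands are supplied the reference competes with them
    in a joint nonnegative unmixing, and only the reference part is
    reported as the contribution.  Without a competing basis, least
    squares attributes any sample intensity overlapping the reference
    bands (e.g. genuine EV Amide I/II) to the reference, which
    systematically over-estimates the contamination.
    """
    y = np.asarray(sample_spectrum, dtype=float)
    if y.shape != axis.values.shape:
        raise ValueError("sample spectrum does not match the axis")
    profiles = np.column_stack([pseudo_voigt(axis.values, b) for b in reference_fit.bands])
    n_ref = profiles.shape[1]
    if ev_basis:
        ev_profiles = np.column_stack([pseudo_voigt(axis.values, b) for b in ev_basis])
        design = np.hstack([profiles, ev_profiles])
    else:
        design = profiles
    if scale_mode == "per-band":
        coefs, _ = optimize.nnls(design, y)
        scales = coefs[:n_ref]
    elif scale_mode == "global":
        total = profiles.sum(axis=1)
        if ev_basis:
            design = np.hstack([total[:, None], design[:, n_ref:]])
            coefs, _ = optimize.nnls(design, y)
            s = coefs[0]
        else:
            denom = float(total @ total)
            s = max(float(total @ y) / denom, 0.0) if denom > 0 else 0.0
        scales = np.full(n_ref, s)
    else:
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    contribution = profiles @ scales
    return scales, contribution


@dataclass
class DeconvolutionResult:
    reference_fit: PeakFit
    scale_amplitudes: np.ndarray
    contribution: np.ndarray
    ev_estimate: np.ndarray
    fraction_removed: float


def default_ev_basis(fwhm: float = 18.0, eta: float = 0.5) -> list:
    """Unit-amplitude bands at every distinct AFM-IR assignment-table
    position (all methods pooled) — the competing basis for unmixing."""
    from .spectra_io import packaged_band_table

    table = packaged_band_table().table
    afm = table[(table["modality"] == "AFM-IR") & (table["method"] != "albumin")]
    centers = sorted(set(afm["wavenumber"].astype(float)))
    return [PseudoVoigtBand(c, fwhm, eta, 1.0) for c in centers]


def deconvolute(
    axis: WavenumberAxis,
    sample_spectrum: np.ndarray,
    reference_spectrum: np.ndarray,
    initial_reference_bands: list | None = None,
    scale_mode: str = "per-band",
    ev_basis: list | None = None,
) -> DeconvolutionResult:
    """Fit the reference as a pseudo-Voigt sum, scale it into the sample,
    and subtract, estimating the reference-free sample spectrum.

    By default the projection competes against unit bands at every
    AFM-IR assignment-table position (see :func:`default_ev_basis`).
    """
    if initial_reference_bands is None:
        initial_reference_bands = pick_initial_bands(axis, reference_spectrum)
    if ev_basis is None:
        ev_basis = default_ev_basis()
    ref_fit = fit_peak_sum(axis, reference_spectrum, initial_reference_bands)
    scales, contribution = project_reference(axis, sample_spectrum, ref_fit, scale_mode,
                                             ev_basis)
    ev = np.asarray(sample_spectrum, dtype=float) - contribution
    denom = float(np.sum(np.abs(sample_spectrum)))
    frac = float(np.sum(np.abs(contribution)) / denom) if denom > 0 else 0.0
    return DeconvolutionResult(ref_fit, scales, contribution, ev, frac)


def assign_peaks(peaks, band_table: BandTable, tolerance: float = 5.0) -> list:
    """Match peak positions to the nearest assignment-table entry.

    ``peaks`` may be a :class:`PeakFit` or an iterable of wavenumbers.
    A peak within ``tolerance`` cm⁻¹ of a table entry (range entries
    match across their full span) takes that entry's assignment; anything
    else is labelled ``"unassigned"``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if isinstance(peaks, PeakFit):
        positions = [b.center for b in peaks.bands]
    else:
        positions = [float(w) for w in peaks]
    tab = band_table.table
    out = []
    for w in positions:
        dist = np.maximum(tab["lo"].to_numpy() - w, w - tab["hi"].to_numpy())
        dist = np.maximum(dist, 0.0)
        j = int(np.argmin(dist))
        if dist[j] <= tolerance:
            out.append((w, str(tab["assignment"].iloc[j])))
        else:
            out.append((w, "unassigned"))
    return out
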