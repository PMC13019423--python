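"""Pseudo-Voigt band model.

IR absorption bands are modelled as a linear mixture of a Gaussian and a
Lorentzian profile sharing one centre and one full width at half maximum
(the common "eta" parameterisation).  Both profiles have unit peak height,
so the band amplitude is the peak intensity at the centre regardless of
the mixing fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PseudoVoigtBand", "WavenumberAxis", "pseudo_voigt", "sum_bands"]

_4LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class PseudoVoigtBand:
    """One spectral band.

    Parameters
    ----------
    center : float
        Band position in cm⁻¹.
    fwhm : float
        Full width at half maximum in cm⁻¹; must be positive.
    eta : float
        Lorentzian mixing fraction in [0, 1]; 1 is pure Lorentzian,
        0 pure Gaussian.
    amplitude : float
        Peak height in (arbitrary) intensity units; must be nonnegative.
    assignment : str
        Optional free-text vibrational assignment.
    """

    center: float
    fwhm: float = 18.0
    eta: float = 0.5
    amplitude: float = 1.0
    assignment: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise ValueError("band center must be finite")
        if not (self.fwhm > 0):
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        if not (self.amplitude >= 0):
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    def scaled(self, factor: float) -> "PseudoVoigtBand":
        """Return a copy with the amplitude multiplied by ``factor``."""
        return PseudoVoigtBand(
            self.center, self.fwhm, self.eta, self.amplitude * factor, self.assignment
        )


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("axis must be a nonempty 1-D array")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("axis values must be finite and positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("axis not increasing")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls, lo: float = 950.0, hi: float = 1920.0, step: float = 2.0) -> "WavenumberAxis":
        """The instrument window 950–1920 cm⁻¹ on a regular grid."""
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )


def pseudo_voigt(x, band: PseudoVoigtBand) -> np.ndarray:
    """Evaluate one pseudo-Voigt band at wavenumber(s) ``x``.

    Returns ``amplitude * (eta * L(x) + (1 - eta) * G(x))`` where the
    Lorentzian L and Gaussian G share the band's FWHM and peak at 1.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    d2 = (x - band.center) ** 2
    hw2 = (band.fwhm / 2.0) ** 2
    lor = hw2 / (hw2 + d2)
    gau = np.exp(-_4LN2 * d2 / band.fwhm**2)
    return band.amplitude * (band.eta * lor + (1.0 - band.eta) * gau)


def sum_bands(axis: WavenumberAxis, bands: list[PseudoVoigtBand]) -> np.ndarray:
    """Pointwise sum of pseudo-Voigt bands on the axis; [] gives zeros."""
    out = np.zeros(len(axis))
    for b in bands:
        out += pseudo_voigt(axis.values, b)
    return out
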