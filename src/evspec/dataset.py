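"""The spectra container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import WavenumberAxis

__all__ = ["SpectraSet"]


@dataclass
class SpectraSet:
    """An n×p intensity matrix on a shared wavenumber axis with group labels.

    Rows are individual particles/spectra, columns are wavenumbers.
    ``labels`` carries the isolation-method group of each row and
    ``sample_ids`` unique row identifiers; ``provenance`` is free-form
    metadata accumulated by the stages that produced the set.
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        labels = np.asarray(self.labels, dtype=object)
        ids = np.asarray(self.sample_ids, dtype=object)
        if X.shape[1] != len(self.axis):
            raise ValueError(
                f"intensity columns ({X.shape[1]}) != axis length ({len(self.axis)})"
            )
        if labels.shape != (X.shape[0],):
            raise ValueError("labels length must equal row count")
        if ids.shape != (X.shape[0],):
            raise ValueError("sample_ids length must equal row count")
        if len(set(ids.tolist())) != ids.size:
            raise ValueError("sample_ids must be unique")
        if X.size and not np.all(np.isfinite(X)):
            raise ValueError("non-finite intensities")
        self.intensities = X
        self.labels = labels
        self.sample_ids = ids

    @property
    def n(self) -> int:
        return self.intensities.shape[0]

    @property
    def groups(self) -> list:
        """Group labels in order of first appearance."""
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def subset(self, mask) -> "SpectraSet":
        """Row subset (boolean mask or index array); axis and metadata kept."""
        mask = np.asarray(mask)
        return SpectraSet(
            self.axis,
            self.intensities[mask],
            self.labels[mask],
            self.sample_ids[mask],
            dict(self.provenance),
        )

    def with_intensities(self, X: np.ndarray, **provenance) -> "SpectraSet":
        """Same rows/axis with a replaced intensity matrix."""
        prov = dict(self.provenance)
        prov.update(provenance)
        return SpectraSet(self.axis, X, self.labels, self.sample_ids, prov)
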