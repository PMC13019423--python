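"""Delimited-text I/O for spectra matrices and band-assignment tables.

The interchange format is deliberately minimal: UTF-8 CSV, one spectrum
per row, header row carrying the wavenumber axis, first two columns
``sample_id`` and ``group``.  Comment lines start with ``#``.  Floats are
written with 17 significant digits so a write→read round trip reproduces
the matrix bit-exactly.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import WavenumberAxis
from .dataset import SpectraSet

__all__ = [
    "BandTable",
    "read_spectra",
    "write_spectra",
    "read_band_table",
    "packaged_band_table",
    "resample",
]

_FLOAT_FMT = "{:.17g}"


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet as CSV (deterministic byte output)."""
    lines = ["# AFM-IR spectra; axis in cm-1; intensities in arbitrary units\n"]
    header = ["sample_id", "group"] + [_FLOAT_FMT.format(w) for w in spectra.axis.values]
    lines.append(",".join(header) + "\n")
    for sid, lab, row in zip(spectra.sample_ids, spectra.labels, spectra.intensities):
        cells = [str(sid), str(lab)] + [_FLOAT_FMT.format(v) for v in row]
        lines.append(",".join(cells) + "\n")
    Path(path).write_text("".join(lines), encoding="utf-8")


def read_spectra(path) -> SpectraSet:
    """Read a spectra CSV written by :func:`write_spectra`.

    Raises ``ValueError`` with a message naming the offending row or
    column for ragged rows, duplicate sample ids, a non-increasing
    wavenumber header, or non-numeric intensities.
    """
    text = Path(path).read_text(encoding="utf-8")
    rows = [
        (i + 1, next(csv.reader([line])))
        for i, line in enumerate(text.splitlines())
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows:
        raise ValueError(f"{path}: empty file")
    _, header = rows[0]
    if len(header) < 3:
        raise ValueError(f"{path}: header must contain sample_id, group and wavenumbers")
    try:
        axis_vals = np.array([float(w) for w in header[2:]])
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric wavenumber in header: {e}") from None
    if np.any(np.diff(axis_vals) <= 0):
        raise ValueError(f"{path}: axis not increasing")
    axis = WavenumberAxis(axis_vals)

    ids, labels, data = [], [], []
    for lineno, cells in rows[1:]:
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(cells)} (ragged row)"
            )
        sid = cells[0]
        if sid in ids:
            raise ValueError(f"{path}: line {lineno}: duplicate sample_id {sid!r}")
        try:
            vals = [float(c) for c in cells[2:]]
        except ValueError:
            bad = next(j for j, c in enumerate(cells[2:]) if not _is_float(c))
            raise ValueError(
                f"{path}: line {lineno}: non-numeric intensity in column "
                f"{header[2 + bad]!r} (value {cells[2 + bad]!r})"
            ) from None
        ids.append(sid)
        labels.append(cells[1])
        data.append(vals)
    X = np.array(data, dtype=float) if data else np.empty((0, len(axis)))
    return SpectraSet(axis, X, np.array(labels, dtype=object), np.array(ids, dtype=object))


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[-–]\s*(\d+(?:\.\d+)?)\s*$")


@dataclass
class BandTable:
    """Band-assignment table: (method, modality, wavenumber-or-range, assignment).

    ``table`` has columns ``method, modality, lo, hi, wavenumber,
    assignment``; single positions have lo == hi == wavenumber, ranges use
    the midpoint as ``wavenumber``.
    """

    table: pd.DataFrame

    def rows_for(self, method: str, modality: str = "AFM-IR") -> pd.DataFrame:
        sel = (self.table["method"] == method) & (self.table["modality"] == modality)
        return self.table[sel].reset_index(drop=True)

    @property
    def methods(self) -> list:
        return sorted(self.table["method"].unique())


def read_band_table(path) -> BandTable:
    """Parse a band table CSV; ranges "a-b" become (a, b) with midpoint."""
    df = pd.read_csv(path, comment="#", dtype=str)
    required = {"method", "modality", "wavenumber", "assignment"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: band table needs columns {sorted(required)}")
    lo, hi, mid = [], [], []
    for i, cell in enumerate(df["wavenumber"]):
        m = _RANGE_RE.match(str(cell))
        if m:
            a, b = sorted((float(m.group(1)), float(m.group(2))))
        elif _is_float(str(cell).strip()):
            a = b = float(cell)
        else:
            raise ValueError(f"{path}: row {i + 2}: unparseable wavenumber {cell!r}")
        lo.append(a)
        hi.append(b)
        mid.append(0.5 * (a + b))
    out = df.assign(lo=lo, hi=hi, wavenumber=mid)
    out["assignment"] = out["assignment"].fillna("")
    return BandTable(out[["method", "modality", "lo", "hi", "wavenumber", "assignment"]])


def packaged_band_table() -> BandTable:
    """The packaged mid-IR assignment table for TEIR/UC/SEC EVs and albumin."""
    ref = resources.files("evspec.data").joinpath("band_table.csv")
    with resources.as_file(ref) as p:
        return read_band_table(p)


def resample(spectra: SpectraSet, target_axis: WavenumberAxis) -> SpectraSet:
    """Linear interpolation of every row onto ``target_axis`` (no extrapolation)."""
    src = spectra.axis.values
    tgt = target_axis.values
    if tgt[0] < src[0] or tgt[-1] > src[-1]:
        raise ValueError(
            f"target axis [{tgt[0]}, {tgt[-1]}] outside source span [{src[0]}, {src[-1]}]"
        )
    if spectra.axis == target_axis:
        return spectra
    X = np.vstack([np.interp(tgt, src, row) for row in spectra.intensities]) if spectra.n else np.empty((0, len(target_axis)))
    return SpectraSet(
        target_axis, X, spectra.labels, spectra.sample_ids,
        {**spectra.provenance, "resampled": True},
    )
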