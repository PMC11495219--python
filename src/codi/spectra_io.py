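"""Containers and I/O for labeled fingerprint spectra on a shared spectral axis.

A *fingerprint* here is a 1-D absorption spectrum (absorbance vs. wavenumber).
Datasets are matrices with one measurement per row on a common wavenumber
axis, plus a class label and a small fixed set of metadata fields per row.

The canonical on-disk dialect is UTF-8 comma-separated text: one header row
whose first columns are the reserved metadata names (``id, label, subject,
visit, specimen, batch, provenance``) followed by the axis values, then one row per
measurement. Floats are written in shortest round-trip representation so a
read/write cycle is byte-identical.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AxisMismatchError,
    DegenerateRowError,
    SpectraFormatError,
    SpectraParseError,
    SpectraValidationError,
)

#: Reserved metadata columns, in canonical on-disk order. ``label`` is stored
#: on :class:`SpectraSet` directly; the rest live in ``meta``.
META_COLUMNS = ("id", "label", "subject", "visit", "specimen", "batch", "provenance")
_META_NONLABEL = tuple(c for c in META_COLUMNS if c != "label")


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered spectral channel positions (wavenumber, cm^-1).

    The axis must be strictly monotonic (either direction); the direction is
    recorded in :attr:`ascending`. All dataset arithmetic is channel-index
    based, so axes are compared, never resampled.
    """

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise SpectraValidationError("axis needs at least 2 channels")
        if not np.all(np.isfinite(vals)):
            raise SpectraValidationError("axis values must be finite")
        d = np.diff(vals)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraValidationError("axis must be strictly monotonic")

    @property
    def n_channels(self) -> int:
        return int(self.values.size)

    @property
    def ascending(self) -> bool:
        return bool(self.values[1] > self.values[0])


def _default_meta(n: int) -> pd.DataFrame:
    return pd.DataFrame({c: [""] * n for c in _META_NONLABEL})


@dataclass
class SpectraSet:
    """A labeled matrix of fingerprints: measurements x channels.

    ``data`` holds absorbance values (a.u.), ``labels`` one class identifier
    per row, and ``meta`` per-row records for the reserved fields
    (subject id, visit, specimen, provenance = experimental|simulated).
    """

    axis: SpectralAxis
    data: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = np.asarray(self.labels, dtype=str)
        if self.data.shape[0] == 0:
            self.data = self.data.reshape(0, self.axis.n_channels)
        if self.meta is None:
            self.meta = _default_meta(self.data.shape[0])
        else:
            self.meta = self.meta.reset_index(drop=True)
            for c in _META_NONLABEL:
                if c not in self.meta.columns:
                    self.meta[c] = ""
            self.meta = self.meta[list(_META_NONLABEL)].astype(str)
        n, p = self.data.shape
        if p != self.axis.n_channels:
            raise SpectraValidationError(
                f"data has {p} channels, axis has {self.axis.n_channels}"
            )
        if self.labels.shape != (n,):
            raise SpectraValidationError("one label per measurement required")
        if len(self.meta) != n:
            raise SpectraValidationError("one meta record per measurement required")
        bad = ~np.isfinite(self.data)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SpectraValidationError(
                f"non-finite value at row {i}, channel {j}"
            )

    # -- container conveniences -------------------------------------------
    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.n_channels

    def select(self, index) -> "SpectraSet":
        """Row subset (bool mask or integer index array), order preserving."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraSet(
            axis=self.axis,
            data=self.data[index],
            labels=self.labels[index],
            meta=self.meta.iloc[index].reset_index(drop=True),
        )

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.axis, self.data.copy(), self.labels.copy(), self.meta.copy())

    @staticmethod
    def concat(sets: "list[SpectraSet]") -> "SpectraSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        first = sets[0]
        for s in sets[1:]:
            assert_same_axis(first, s)
        return SpectraSet(
            axis=first.axis,
            data=np.vstack([s.data for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            meta=pd.concat([s.meta for s in sets], ignore_index=True),
        )

    def subjects(self) -> np.ndarray:
        return np.unique(self.meta["subject"].to_numpy())


def _fmt(x: float) -> str:
    """Shortest representation that round-trips through float()."""
    return repr(float(x))


def write_spectra(s: SpectraSet, path, dialect: str = "csv"):
    """Write a :class:`SpectraSet` in the canonical delimited dialect.

    Axis and data values are written at full precision (shortest float repr),
    so :func:`read_spectra` followed by ``write_spectra`` is byte-identical.
    """
    if dialect != "csv":
        raise SpectraFormatError(f"unknown dialect: {dialect!r}")
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(list(META_COLUMNS) + [_fmt(v) for v in s.axis.values])
    for i in range(s.n):
        m = s.meta.iloc[i]
        row = [m["id"], s.labels[i], m["subject"], m["visit"], m["specimen"],
               m["batch"], m["provenance"]]
        row += [_fmt(v) for v in s.data[i]]
        w.writerow(row)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
    return path


def read_spectra(path, dialect: str = "csv") -> SpectraSet:
    """Read a canonical delimited fingerprint file into a :class:`SpectraSet`."""
    if dialect != "csv":
        raise SpectraFormatError(f"unknown dialect: {dialect!r}")
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise SpectraFormatError("empty file: no axis header")
    header = rows[0]
    if tuple(header[: len(META_COLUMNS)]) != META_COLUMNS:
        raise SpectraFormatError(
            f"header must start with {','.join(META_COLUMNS)}"
        )
    axis_cells = header[len(META_COLUMNS):]
    if not axis_cells:
        raise SpectraFormatError("missing axis values in header")
    try:
        axis = SpectralAxis(np.array([float(c) for c in axis_cells]))
    except ValueError as e:
        raise SpectraFormatError(f"non-numeric axis header: {e}") from None
    p = axis.n_channels
    n = len(rows) - 1
    data = np.empty((n, p))
    labels, meta_rows = [], []
    na_tokens = {"", "NA", "N/A", "NaN", "nan", "NAN", "null", "NULL"}
    for i, row in enumerate(rows[1:]):
        if len(row) != len(META_COLUMNS) + p:
            raise SpectraParseError(
                f"ragged row {i}: expected {len(META_COLUMNS) + p} fields, got {len(row)}"
            )
        rid, label, subject, visit, specimen, batch, provenance = row[: len(META_COLUMNS)]
        labels.append(label)
        meta_rows.append((rid, subject, visit, specimen, batch, provenance))
        for j, cell in enumerate(row[len(META_COLUMNS):]):
            if cell in na_tokens:
                raise SpectraValidationError(
                    f"missing value at row {i}, channel {j}"
                )
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise SpectraParseError(
                    f"non-numeric value {cell!r} at row {i}, channel {j}"
                ) from None
    meta = pd.DataFrame(meta_rows, columns=list(_META_NONLABEL))
    if n == 0:
        meta = _default_meta(0)
    return SpectraSet(axis=axis, data=data, labels=np.array(labels, dtype=str), meta=meta)


def assert_same_axis(a: SpectraSet | SpectralAxis, b: SpectraSet | SpectralAxis,
                     tol: float = 1e-9) -> bool:
    """True iff the two spectral axes agree element-wise within relative ``tol``.

    Differing channel counts raise :class:`AxisMismatchError` rather than
    returning False: index-wise arithmetic would be meaningless, not merely
    shifted. Never mutates its arguments; symmetric.
    """
    ax_a = a.axis if isinstance(a, SpectraSet) else a
    ax_b = b.axis if isinstance(b, SpectraSet) else b
    if ax_a.n_channels != ax_b.n_channels:
        raise AxisMismatchError(
            f"axis lengths differ: {ax_a.n_channels} vs {ax_b.n_channels}"
        )
    return bool(np.allclose(ax_a.values, ax_b.values, rtol=tol, atol=0.0))


def vector_normalize(s: SpectraSet) -> SpectraSet:
    """Scale every measurement to unit Euclidean norm (labels/meta preserved).

    This is the package's single opt-in preprocessing step; it must be applied
    identically to train, test and calibration sets when used at all.
    """
    norms = np.linalg.norm(s.data, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise DegenerateRowError(f"zero-norm row {zero[0]} cannot be normalized")
    return SpectraSet(s.axis, s.data / norms[:, None], s.labels.copy(), s.meta.copy())
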