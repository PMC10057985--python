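"""Spectral data model and I/O.

A :class:`SpectrumSet` is the package's central container: an N × P absorbance
matrix on a shared wavenumber grid, with per-sample class labels and unique
ids.  Instruments report NIR grids in descending wavenumber order
(12,000 → 4,000 cm⁻¹) and that order is preserved throughout; only the
Savitzky–Golay derivatives care about the sign of the grid step.

Storage format is a wide CSV — one row per sample, columns ``id``, ``label``,
then the wavenumbers as numeric headers — the shape in which exported
spectrometer tables are usually exchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GridError, ParseError, ParameterError

#: Instrument-default spectral range in cm⁻¹ (diffuse-reflectance NIR).
DEFAULT_RANGE = (12_000.0, 4_000.0)


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly monotonic wavenumber axis in cm⁻¹.

    Parameters
    ----------
    values
        Wavenumbers, conventionally stored descending (12,000 → 4,000 cm⁻¹)
        as instruments report them.  Any strictly monotonic positive axis is
        accepted; the number of points is not hard-coded.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise GridError("grid needs at least two wavenumbers")
        d = np.diff(v)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise GridError("wavenumber grid must be strictly monotonic")
        if np.any(v <= 0):
            raise GridError("wavenumbers must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        """Mean signed spacing in cm⁻¹ (negative for descending grids)."""
        return float(np.mean(np.diff(self.values)))

    @property
    def descending(self) -> bool:
        return self.values[0] > self.values[-1]

    @classmethod
    def default(cls, n_points: int = 2074,
                high: float = DEFAULT_RANGE[0],
                low: float = DEFAULT_RANGE[1]) -> "WavenumberGrid":
        """Instrument-default descending grid over 12,000–4,000 cm⁻¹."""
        if n_points < 2:
            raise ParameterError("n_points must be >= 2")
        return cls(np.linspace(high, low, n_points))

    def __eq__(self, other) -> bool:  # value equality, used for grid checks
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values)

    def __hash__(self):
        return hash((self.values.shape, float(self.values[0]),
                     float(self.values[-1])))


@dataclass
class SpectrumSet:
    """Labeled collection of absorbance spectra on a shared grid.

    ``absorbance`` is N × P (dimensionless absorbance, log 1/R, assumed
    already computed by the instrument); ``labels`` carries at most two
    distinct class tags in a classification run (e.g. ``ZJ`` / ``nonZJ``);
    ``ids`` are unique per sample.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    labels: np.ndarray
    ids: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            a = a.reshape(-1, len(self.grid))
        if a.shape[1] != len(self.grid):
            raise ParameterError(
                f"absorbance has {a.shape[1]} columns, grid has {len(self.grid)}")
        if not np.all(np.isfinite(a)):
            bad = np.argwhere(~np.isfinite(a))[0]
            raise ParseError(f"non-finite absorbance at row {bad[0]}, column {bad[1]}")
        labels = np.asarray(self.labels, dtype=object)
        ids = np.asarray(self.ids, dtype=object)
        if labels.shape != (a.shape[0],) or ids.shape != (a.shape[0],):
            raise ParameterError("labels and ids must have one entry per spectrum")
        if len(set(ids.tolist())) != ids.size:
            raise ParameterError("sample ids must be unique")
        if len(set(labels.tolist())) > 2:
            raise ParameterError("at most two distinct class labels are supported")
        self.absorbance = a
        self.labels = labels
        self.ids = ids

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    @property
    def classes(self) -> list:
        """Distinct labels in sorted order (tie-break order for classifiers)."""
        return sorted(set(self.labels.tolist()))

    def with_absorbance(self, a: np.ndarray) -> "SpectrumSet":
        """Same samples/grid with a transformed absorbance matrix."""
        return SpectrumSet(self.grid, a, self.labels.copy(), self.ids.copy())

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        return subset(self, indices)

    def class_codes(self, positive_class=None) -> np.ndarray:
        """Labels as float {0, 1}.

        The positive class (code 1) defaults to the last label in sorted
        order; pass ``positive_class`` explicitly when the coding convention
        matters (e.g. Zhejiang as the positive origin).
        """
        cls = self.classes
        if positive_class is None:
            positive_class = cls[-1]
        return (self.labels == positive_class).astype(float)


def subset(s: SpectrumSet, indices: Iterable[int]) -> SpectrumSet:
    """Row-select samples in the given order; the grid is shared, not copied.

    Raises ``IndexError`` for out-of-range indices and ``ParameterError`` for
    duplicates (which would break id uniqueness).
    """
    idx = np.asarray(list(indices), dtype=int)
    if idx.size and (idx.max() >= s.n_samples or idx.min() < -s.n_samples):
        raise IndexError(f"subset index out of range for N={s.n_samples}")
    if len(set(idx.tolist())) != idx.size:
        raise ParameterError("subset indices must be unique")
    return SpectrumSet(s.grid, s.absorbance[idx], s.labels[idx], s.ids[idx])


def write_spectra(s: SpectrumSet, path) -> None:
    """Write a wide CSV: id, label, then wavenumber columns in grid order.

    Values are written with Python's shortest round-tripping float repr, so
    ``read_spectra(write_spectra(s))`` restores the matrix bitwise.
    """
    path = Path(path)
    cols = ["id", "label"] + [repr(float(v)) for v in s.grid.values]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(cols) + "\n")
        for i in range(s.n_samples):
            row = [str(s.ids[i]), str(s.labels[i])]
            row += [repr(float(x)) for x in s.absorbance[i]]
            fh.write(",".join(row) + "\n")


def read_spectra(path, fmt: str = "wide-csv") -> SpectrumSet:
    """Read a wide CSV produced by :func:`write_spectra` (or any table with an
    ``id`` column, a ``label`` column, and numeric wavenumber headers)."""
    if fmt != "wide-csv":
        raise ParameterError(f"unsupported format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectra file not found: {path}")
    df = pd.read_csv(path, dtype={"id": str, "label": str},
                     float_precision="round_trip")
    for required in ("id", "label"):
        if required not in df.columns:
            raise ParseError(f"missing required column {required!r}")
    spec_cols = [c for c in df.columns if c not in ("id", "label")]
    try:
        wavenumbers = np.array([float(c) for c in spec_cols])
    except ValueError as e:
        raise ParseError(f"non-numeric wavenumber header: {e}") from None
    try:
        grid = WavenumberGrid(wavenumbers)
    except GridError:
        raise
    mat = np.empty((len(df), len(spec_cols)))
    for j, c in enumerate(spec_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise ParseError(
                f"missing or non-numeric absorbance at row {i} "
                f"(id={df['id'].iloc[i]!r}), column {c!r}")
        mat[:, j] = col.to_numpy()
    return SpectrumSet(grid, mat, df["label"].to_numpy(dtype=object),
                       df["id"].to_numpy(dtype=object))
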