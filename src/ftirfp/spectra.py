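"""Core spectral data model: spectra, aligned sets, windows, CSV I/O.

A :class:`Spectrum` is a single absorbance trace on an ascending wavenumber
axis with donor/replicate/group metadata. A :class:`SpectraSet` is a
collection of spectra sharing one grid — the universal currency of the
pipeline. All downstream stages (QC, preprocessing, classification,
exploration) consume and produce ``SpectraSet`` objects.

The exchange format is a wide CSV: header ``donor_id,replicate_id,group``
followed by the wavenumber columns in ascending order; one row per
(donor, replicate) pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Spectrum",
    "SpectraSet",
    "Window",
    "FINGERPRINT",
    "AMIDE_I",
    "OFFBAND_PRIMARY",
    "OFFBAND_FALLBACK",
    "SpectraFormatError",
    "AlignmentError",
    "WindowError",
    "MetadataError",
    "read_spectra_csv",
    "write_spectra_csv",
    "align_axes",
    "aggregate_replicates",
    "extract_window",
]

REPLICATE_MEAN = "mean"  # sentinel replicate_id after donor-level aggregation


class SpectraFormatError(ValueError):
    """Malformed spectra file or matrix (non-monotone grid, bad cells, duplicates)."""


class AlignmentError(ValueError):
    """Wavenumber axes cannot be brought onto a common grid."""


class WindowError(ValueError):
    """A spectral window selects no grid points."""


class MetadataError(ValueError):
    """Inconsistent donor/replicate/group metadata."""


class Group(str, Enum):
    """Donor pathway label.

    DCD: donation after circulatory death. DBD: donation after brain death.
    Labels outside these two load as UNKNOWN; supervised stages reject
    UNKNOWN rows while label-free stages (QC, exploration) accept them.
    """

    DCD = "DCD"
    DBD = "DBD"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, label: object) -> "Group":
        if isinstance(label, cls):
            return label
        s = str(label).strip().upper()
        if s == "DCD":
            return cls.DCD
        if s == "DBD":
            return cls.DBD
        return cls.UNKNOWN


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace with metadata.

    Invariants: ``wavenumbers`` strictly increasing, same length as
    ``absorbance`` (≥ 2 points), all values finite.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    donor_id: str = ""
    replicate_id: str = "0"
    group: Group = Group.UNKNOWN

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        if wn.ndim != 1 or ab.ndim != 1 or wn.shape != ab.shape:
            raise SpectraFormatError("wavenumbers and absorbance must be 1-D and equal length")
        if wn.size < 2:
            raise SpectraFormatError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wn) > 0):
            raise SpectraFormatError("wavenumber axis must be strictly increasing")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(ab))):
            raise SpectraFormatError("non-finite values in spectrum")

    @property
    def n_points(self) -> int:
        return int(self.wavenumbers.size)


@dataclass
class SpectraSet:
    """Axis-aligned spectra: shared grid, n×p matrix, per-row metadata.

    ``meta`` has columns ``donor_id``, ``replicate_id``, ``group`` (a
    :class:`Group` per row); (donor_id, replicate_id) pairs are unique.
    """

    grid: np.ndarray
    matrix: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not np.all(np.diff(self.grid) > 0):
            raise SpectraFormatError("grid must be strictly increasing")
        if self.matrix.shape != (len(self.meta), self.grid.size):
            raise SpectraFormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.meta)} rows x {self.grid.size} grid points"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise SpectraFormatError("non-finite absorbance values")
        required = {"donor_id", "replicate_id", "group"}
        if not required.issubset(self.meta.columns):
            raise MetadataError(f"meta must have columns {sorted(required)}")
        self.meta = self.meta.reset_index(drop=True)
        self.meta["group"] = self.meta["group"].map(Group.parse)
        pairs = list(zip(self.meta["donor_id"], self.meta["replicate_id"]))
        if len(set(pairs)) != len(pairs):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise MetadataError(f"duplicate (donor_id, replicate_id) pairs: {dupes}")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size

    def row(self, i: int) -> Spectrum:
        m = self.meta.iloc[i]
        return Spectrum(self.grid, self.matrix[i], m["donor_id"], m["replicate_id"], m["group"])

    def spectra(self) -> Iterator[Spectrum]:
        for i in range(self.n_spectra):
            yield self.row(i)

    def groups(self) -> np.ndarray:
        return np.array([g for g in self.meta["group"]], dtype=object)

    def subset(self, idx: Sequence[int]) -> "SpectraSet":
        idx = list(idx)
        return SpectraSet(self.grid, self.matrix[idx], self.meta.iloc[idx].copy())


@dataclass(frozen=True)
class Window:
    """Closed wavenumber interval [lo, hi] in cm⁻¹."""

    lo: float
    hi: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise WindowError(f"window lo must be < hi, got [{self.lo}, {self.hi}]")

    def mask(self, grid: np.ndarray) -> np.ndarray:
        return (grid >= self.lo) & (grid <= self.hi)


# Fixed analysis windows (cm⁻¹). The fingerprint region integrates lipid,
# carbohydrate, phosphate and protein side-chain bands; Amide I is dominated
# by the protein backbone C=O stretch; the off-band windows are used for
# noise estimation, nominally signal-free in dried biofluid films.
FINGERPRINT = Window(900.0, 1800.0, "fingerprint")
AMIDE_I = Window(1600.0, 1700.0, "amide_i")
OFFBAND_PRIMARY = Window(1800.0, 1900.0, "offband_primary")
OFFBAND_FALLBACK = Window(2000.0, 2200.0, "offband_fallback")

NAMED_WINDOWS = {
    "fingerprint": FINGERPRINT,
    "amide_i": AMIDE_I,
    "offband_primary": OFFBAND_PRIMARY,
    "offband_fallback": OFFBAND_FALLBACK,
}


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_META_COLS = ("donor_id", "replicate_id", "group")


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide spectra CSV into a :class:`SpectraSet`.

    Header must start ``donor_id,replicate_id,group`` followed by numeric
    wavenumber column names in strictly ascending order. Group strings are
    mapped case-insensitively onto {DCD, DBD}; anything else becomes UNKNOWN.
    """
    df = pd.read_csv(path, dtype={"donor_id": str, "replicate_id": str})
    cols = list(df.columns)
    if tuple(cols[:3]) != _META_COLS:
        raise SpectraFormatError(
            f"header must begin {','.join(_META_COLS)}; got {cols[:3]}"
        )
    try:
        grid = np.array([float(c) for c in cols[3:]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber column name: {exc}") from exc
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise SpectraFormatError("wavenumber columns must be strictly ascending")
    values = df.iloc[:, 3:]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~values.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SpectraFormatError(
            f"non-numeric absorbance at row {r}, column {cols[3 + c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise SpectraFormatError(f"missing absorbance at row {r}, column {cols[3 + c]!r}")
    meta = df[list(_META_COLS)].copy()
    return SpectraSet(grid, numeric.to_numpy(dtype=float), meta)


def write_spectra_csv(spectra_set: SpectraSet, path) -> None:
    """Write a :class:`SpectraSet` as a wide CSV (inverse of :func:`read_spectra_csv`).

    Wavenumber column names are printed with ≤ 4 decimals; absorbance values
    at full float precision so write∘read round-trips within 1e-12.
    """
    names = [_format_wavenumber(v) for v in spectra_set.grid]
    df = pd.DataFrame(spectra_set.matrix, columns=names)
    meta = spectra_set.meta.copy()
    meta["group"] = [g.value for g in meta["group"]]
    out = pd.concat([meta[list(_META_COLS)].reset_index(drop=True), df], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")


def _format_wavenumber(v: float) -> str:
    s = f"{v:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"


# ---------------------------------------------------------------------------
# Axis alignment, aggregation, windowing
# ---------------------------------------------------------------------------

def align_axes(
    spectra: Iterable[Spectrum], target_grid: np.ndarray | None = None
) -> SpectraSet:
    """Linearly interpolate spectra onto a shared grid; never extrapolate.

    Default target: the common overlap of all axes sampled at the first
    spectrum's (median) spacing. With an explicit ``target_grid``, the grid
    is restricted to the overlap so no point is extrapolated.
    """
    spectra = list(spectra)
    if not spectra:
        raise AlignmentError("no spectra to align")
    lo = max(s.wavenumbers[0] for s in spectra)
    hi = min(s.wavenumbers[-1] for s in spectra)
    if lo >= hi:
        raise AlignmentError(f"wavenumber axes have empty overlap ([{lo}, {hi}])")
    if target_grid is None:
        step = float(np.median(np.diff(spectra[0].wavenumbers)))
        grid = lo + step * np.arange(int(np.floor((hi - lo) / step + 1e-9)) + 1)
    else:
        tg = np.asarray(target_grid, dtype=float)
        grid = tg[(tg >= lo) & (tg <= hi)]
        if grid.size < 2:
            raise AlignmentError("target grid has <2 points inside the common overlap")
    matrix = np.empty((len(spectra), grid.size))
    for i, s in enumerate(spectra):
        matrix[i] = np.interp(grid, s.wavenumbers, s.absorbance)
    meta = pd.DataFrame(
        {
            "donor_id": [s.donor_id for s in spectra],
            "replicate_id": [s.replicate_id for s in spectra],
            "group": [s.group for s in spectra],
        }
    )
    return SpectraSet(grid, matrix, meta)


def aggregate_replicates(spectra_set: SpectraSet) -> SpectraSet:
    """Average technical replicates to one spectrum per donor.

    Rows are ordered by donor_id; replicate_id becomes the sentinel ``mean``.
    Raises :class:`MetadataError` if a donor carries conflicting group labels.
    """
    meta = spectra_set.meta
    donors = sorted(meta["donor_id"].unique())
    rows, groups = [], []
    for donor in donors:
        idx = np.flatnonzero((meta["donor_id"] == donor).to_numpy())
        donor_groups = {meta.iloc[i]["group"] for i in idx}
        if len(donor_groups) != 1:
            raise MetadataError(
                f"donor {donor!r} has conflicting group labels: "
                f"{sorted(g.value for g in donor_groups)}"
            )
        rows.append(spectra_set.matrix[idx].mean(axis=0))
        groups.append(donor_groups.pop())
    new_meta = pd.DataFrame(
        {
            "donor_id": donors,
            "replicate_id": [REPLICATE_MEAN] * len(donors),
            "group": groups,
        }
    )
    return SpectraSet(spectra_set.grid, np.array(rows), new_meta)


def extract_window(
    spectra_set: SpectraSet, window: Window, margin_points: int = 0
) -> SpectraSet:
    """Keep columns with lo ≤ ν ≤ hi (closed bounds), ± an optional margin.

    ``margin_points`` widens the selection per side where the grid allows
    (used to absorb Savitzky–Golay edge loss); near grid edges the margin is
    truncated rather than extrapolated.
    """
    mask = window.mask(spectra_set.grid)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise WindowError(
            f"window [{window.lo}, {window.hi}] selects no grid points "
            f"(grid spans [{spectra_set.grid[0]}, {spectra_set.grid[-1]}])"
        )
    lo = max(0, idx[0] - int(margin_points))
    hi = min(spectra_set.n_points, idx[-1] + 1 + int(margin_points))
    sel = slice(lo, hi)
    return SpectraSet(spectra_set.grid[sel], spectra_set.matrix[:, sel], spectra_set.meta.copy())
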