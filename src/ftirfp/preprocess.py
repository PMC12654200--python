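"""Spectral preprocessing: rubber-band baseline, SG derivatives, VN, pipelines.

The preprocessing ladder evaluated by the pipeline consists of rubber-band
(lower convex hull) baseline correction, Savitzky–Golay first and second
derivatives (second-order polynomial, 15-point window), vector
normalization to unit Euclidean norm, and their named compositions. All
steps are per-spectrum (no cross-sample statistics), so applying them before
a cross-validation split leaks no information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import (
    AMIDE_I,
    FINGERPRINT,
    SpectraSet,
    Spectrum,
    Window,
    extract_window,
)

__all__ = [
    "PipelineSpec",
    "PIPELINE_NAMES",
    "rubberband_baseline",
    "rubberband_correct",
    "savgol_derivative",
    "vector_normalize",
    "apply_pipeline",
    "NormalizationError",
    "GridError",
]

SG_WINDOW = 15
SG_POLY = 2
SG_EDGE = SG_WINDOW // 2  # points lost per side by edge truncation


class NormalizationError(ValueError):
    """Vector normalization of a (near-)zero spectrum."""


class GridError(ValueError):
    """Operation requires a uniformly spaced grid."""


# ---------------------------------------------------------------------------
# Rubber-band (lower convex hull) baseline
# ---------------------------------------------------------------------------

def lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices of the point set (x, y).

    Andrew monotone-chain lower pass; x must be strictly increasing.
    Collinear interior points are dropped (the interpolated baseline is
    unchanged).
    """
    n = x.size
    stack: list[int] = []
    for i in range(n):
        while len(stack) >= 2:
            o, a = stack[-2], stack[-1]
            cross = (x[a] - x[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (x[i] - x[o])
            if cross <= 0:  # non-convex (or collinear) turn: pop
                stack.pop()
            else:
                break
        stack.append(i)
    return np.array(stack, dtype=int)


def rubberband_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Baseline = lower convex hull of (x, y), linearly interpolated."""
    idx = lower_hull_indices(np.asarray(x, float), np.asarray(y, float))
    return np.interp(x, x[idx], y[idx])


def rubberband_correct(spectrum: Spectrum) -> Spectrum:
    """Subtract the rubber-band baseline; result ≥ 0 at hull vertices."""
    corrected = spectrum.absorbance - rubberband_baseline(
        spectrum.wavenumbers, spectrum.absorbance
    )
    return Spectrum(
        spectrum.wavenumbers, corrected, spectrum.donor_id, spectrum.replicate_id, spectrum.group
    )


def _rubberband_matrix(grid: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    return np.array([row - rubberband_baseline(grid, row) for row in matrix])


# ---------------------------------------------------------------------------
# Savitzky–Golay derivatives
# ---------------------------------------------------------------------------

def _check_uniform(grid: np.ndarray) -> float:
    d = np.diff(grid)
    h = float(np.mean(d))
    if np.max(np.abs(d - h)) > 1e-9 * max(abs(h), 1.0):
        raise GridError("Savitzky–Golay derivative requires a uniformly spaced grid")
    return h


def _savgol_matrix(
    grid: np.ndarray,
    matrix: np.ndarray,
    deriv_order: int,
    window_points: int = SG_WINDOW,
    poly_order: int = SG_POLY,
) -> tuple[np.ndarray, np.ndarray]:
    if deriv_order not in (1, 2):
        raise ValueError("deriv_order must be 1 or 2")
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if window_points <= poly_order:
        raise ValueError("window_points must exceed poly_order")
    if window_points > grid.size:
        raise ValueError(
            f"window of {window_points} points exceeds spectrum length {grid.size}"
        )
    h = _check_uniform(grid)
    d = savgol_filter(
        matrix, window_points, poly_order, deriv=deriv_order, delta=h, axis=-1
    )
    edge = window_points // 2
    # the convolutional coefficients are only valid on full interior windows;
    # edges are truncated rather than padded
    return grid[edge:-edge], d[..., edge:-edge]


def savgol_derivative(
    spectrum: Spectrum,
    deriv_order: int,
    window_points: int = SG_WINDOW,
    poly_order: int = SG_POLY,
) -> Spectrum:
    """Savitzky–Golay smoothed derivative with respect to wavenumber.

    The result is scaled by the grid spacing (true d/dν units) and the
    window half-width is dropped at each edge — the output grid shrinks.
    """
    grid, d = _savgol_matrix(
        spectrum.wavenumbers, spectrum.absorbance[None, :], deriv_order, window_points, poly_order
    )
    return Spectrum(grid, d[0], spectrum.donor_id, spectrum.replicate_id, spectrum.group)


# ---------------------------------------------------------------------------
# Vector normalization
# ---------------------------------------------------------------------------

def vector_normalize(spectrum: Spectrum, center_first: bool = False) -> Spectrum:
    """Scale to unit Euclidean norm (optionally mean-centering first)."""
    y = spectrum.absorbance
    if center_first:
        y = y - y.mean()
    norm = float(np.linalg.norm(y))
    if norm <= 0:
        raise NormalizationError("cannot vector-normalize a zero spectrum")
    return Spectrum(
        spectrum.wavenumbers, y / norm, spectrum.donor_id, spectrum.replicate_id, spectrum.group
    )


def _vn_matrix(matrix: np.ndarray, center_first: bool = False) -> np.ndarray:
    m = matrix - matrix.mean(axis=1, keepdims=True) if center_first else matrix
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms <= 0):
        raise NormalizationError("cannot vector-normalize a zero spectrum")
    return m / norms


# ---------------------------------------------------------------------------
# Named pipelines
# ---------------------------------------------------------------------------

_STEPS = ("rubberband_bc", "vector_norm", "sg_deriv_1", "sg_deriv_2")

# CLI slugs -> (steps, fcbf flag); canonical display labels alongside
PIPELINE_NAMES: dict[str, tuple[tuple[str, ...], bool]] = {
    "bc": (("rubberband_bc",), False),
    "vn": (("vector_norm",), False),
    "d1": (("sg_deriv_1",), False),
    "d1+vn": (("sg_deriv_1", "vector_norm"), False),
    "d2": (("sg_deriv_2",), False),
    "d2+fcbf": (("sg_deriv_2",), True),
}

PIPELINE_LABELS = {
    "bc": "Rubber band BC",
    "vn": "VN",
    "d1": "1st derivative",
    "d1+vn": "1st derivative + VN",
    "d2": "2nd derivative",
    "d2+fcbf": "2nd derivative + FCBF",
}

_REGIONS = {"fingerprint": FINGERPRINT, "amide_i": AMIDE_I}


@dataclass(frozen=True)
class PipelineSpec:
    """A named preprocessing pipeline on a spectral region.

    ``fcbf`` marks whether FCBF feature selection is applied downstream (it
    is not a preprocessing step itself — selection happens inside the
    cross-validation loop).
    """

    region: str
    steps: tuple[str, ...]
    fcbf: bool = False

    def __post_init__(self) -> None:
        if self.region not in _REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not self.steps:
            raise ValueError("pipeline needs at least one step")
        for s in self.steps:
            if s not in _STEPS:
                raise ValueError(f"unknown step {s!r}")
        n_deriv = sum(s.startswith("sg_deriv") for s in self.steps)
        if n_deriv > 1:
            raise ValueError("at most one derivative step per pipeline")

    @classmethod
    def from_name(cls, name: str, region: str) -> "PipelineSpec":
        key = name.strip().lower()
        if key not in PIPELINE_NAMES:
            raise ValueError(
                f"unknown pipeline {name!r}; expected one of {sorted(PIPELINE_NAMES)}"
            )
        steps, fcbf = PIPELINE_NAMES[key]
        return cls(region=region, steps=steps, fcbf=fcbf)

    @property
    def window(self) -> Window:
        return _REGIONS[self.region]

    @property
    def has_derivative(self) -> bool:
        return any(s.startswith("sg_deriv") for s in self.steps)

    @property
    def name(self) -> str:
        for key, (steps, fcbf) in PIPELINE_NAMES.items():
            if steps == self.steps and fcbf == self.fcbf:
                return key
        return "+".join(self.steps)


def apply_pipeline(spectra_set: SpectraSet, spec: PipelineSpec) -> SpectraSet:
    """Apply the pipeline's steps, in order, to every row of the set.

    The region window is extracted first (with a half-window margin when a
    derivative step is present, so the edge loss falls outside the region
    where the grid allows); after all steps the result is re-restricted to
    the region window.
    """
    margin = SG_EDGE if spec.has_derivative else 0
    work = extract_window(spectra_set, spec.window, margin_points=margin)
    grid, matrix = work.grid, work.matrix
    for i, step in enumerate(spec.steps):
        try:
            if step == "rubberband_bc":
                matrix = _rubberband_matrix(grid, matrix)
            elif step == "vector_norm":
                matrix = _vn_matrix(matrix)
            elif step == "sg_deriv_1":
                grid, matrix = _savgol_matrix(grid, matrix, 1)
            elif step == "sg_deriv_2":
                grid, matrix = _savgol_matrix(grid, matrix, 2)
        except Exception as exc:
            raise type(exc)(f"pipeline step {i} ({step}): {exc}") from exc
    out = SpectraSet(grid, matrix, work.meta.copy())
    mask = spec.window.mask(grid)
    if mask.any() and not mask.all():
        out = extract_window(out, spec.window)
    return out
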