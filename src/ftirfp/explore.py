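"""Unsupervised structure and generalized 2D correlation spectroscopy.

Cosine distances between donor-level spectra feed a classical-scaling +
SMACOF multidimensional scaling embedding and Ward hierarchical clustering.
Generalized 2D correlation spectroscopy (2D-COS) decomposes band
co-variation across the sample series into a synchronous map (in-phase,
ỸᵀỸ/(m−1)) and an asynchronous map (out-of-phase, ỸᵀNỸ/(m−1) with the
Hilbert–Noda transform matrix N).

For a cross-sectional cohort the 2D-COS "perturbation" axis is a sample
ordering, not a physical variable; the default orders rows in group blocks
(DBD first, then DCD), by donor id within a block, and the ordering is
configurable and recorded because the asynchronous map depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .spectra import Group, SpectraSet

__all__ = [
    "DistanceMatrix",
    "MDSResult",
    "CorrelationMaps",
    "cosine_distance_matrix",
    "mds_embed",
    "ward_cluster",
    "twodcos_maps",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class MDSResult:
    coords: np.ndarray
    stress: float
    stress_history: list[float]


@dataclass
class CorrelationMaps:
    """2D-COS output: sync symmetric, async antisymmetric with zero diagonal."""

    grid: np.ndarray
    sync: np.ndarray
    async_: np.ndarray
    order: list[str]


def cosine_distance_matrix(spectra_set: SpectraSet) -> DistanceMatrix:
    """d(i, j) = 1 − cos(xᵢ, xⱼ); entries lie in [0, 2]."""
    X = spectra_set.matrix
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = spectra_set.meta["donor_id"][norms == 0].tolist()
        raise ValueError(f"zero-norm rows have no direction: {bad}")
    U = X / norms[:, None]
    d = 1.0 - U @ U.T
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return DistanceMatrix(spectra_set.meta["donor_id"].tolist(), d)


def _smacof_stress(X: np.ndarray, delta: np.ndarray) -> float:
    diff = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    return float(((diff - delta) ** 2)[np.triu_indices_from(delta, 1)].sum())


def mds_embed(
    dm: DistanceMatrix, dims: int = 2, seed: int = 0, max_iter: int = 300, tol: float = 1e-9
) -> MDSResult:
    """Metric MDS: classical-scaling initialization + SMACOF majorization.

    The classical (Torgerson) solution initializes the configuration;
    Guttman-transform iterations then minimize raw stress until the relative
    stress change falls below ``tol`` or ``max_iter`` iterations. The
    procedure is deterministic (``seed`` is accepted for interface
    stability; no randomness is used).
    """
    delta = dm.d
    n = dm.n
    if np.allclose(delta, 0.0):
        return MDSResult(np.zeros((n, dims)), 0.0, [0.0])
    # Torgerson: double-center the squared distances
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (delta**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:dims]
    L = np.sqrt(np.clip(w[idx], 0.0, None))
    X = V[:, idx] * L[None, :]
    stress = _smacof_stress(X, delta)
    history = [stress]
    for _ in range(max_iter):
        diff = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(diff > 0, delta / diff, 0.0)
        Bmat = -ratio
        np.fill_diagonal(Bmat, 0.0)
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        X = Bmat @ X / n
        new_stress = _smacof_stress(X, delta)
        history.append(new_stress)
        if stress > 0 and (stress - new_stress) / stress < tol:
            stress = new_stress
            break
        stress = new_stress
    return MDSResult(X, stress, history)


def ward_cluster(dm: DistanceMatrix) -> np.ndarray:
    """Ward agglomeration on the given distances (Lance–Williams update).

    Returns a scipy-format linkage matrix (merge pairs, heights, sizes).
    Cosine distances are not Euclidean, so this is Ward's recursion applied
    to the supplied dissimilarities as-is — heights remain monotone
    non-decreasing under the D2 update.
    """
    if dm.n < 2:
        raise ValueError("clustering needs at least 2 items")
    return linkage(squareform(dm.d, checks=False), method="ward")


def noda_matrix(m: int) -> np.ndarray:
    """Hilbert–Noda transform matrix: N(j,k) = 1/(π(k−j)) off the diagonal."""
    j, k = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    with np.errstate(divide="ignore"):
        N = 1.0 / (np.pi * (k - j))
    N[j == k] = 0.0
    return N


def perturbation_order(spectra_set: SpectraSet) -> np.ndarray:
    """Default 2D-COS sample ordering: DBD block first, then DCD, by donor id."""
    rank = {Group.DBD: 0, Group.DCD: 1, Group.UNKNOWN: 2}
    keys = [
        (rank[spectra_set.meta.iloc[i]["group"]], spectra_set.meta.iloc[i]["donor_id"],
         spectra_set.meta.iloc[i]["replicate_id"])
        for i in range(spectra_set.n_spectra)
    ]
    return np.array(sorted(range(len(keys)), key=keys.__getitem__))


def twodcos_maps(
    spectra_set: SpectraSet, order: np.ndarray | None = None
) -> CorrelationMaps:
    """Synchronous and asynchronous 2D correlation maps.

    Dynamic spectra Ỹ = rows − mean spectrum, taken in the declared sample
    order; sync = ỸᵀỸ/(m−1); async = ỸᵀNỸ/(m−1). Symmetry (sync) and
    antisymmetry with zero diagonal (async) are enforced exactly.
    """
    if spectra_set.n_spectra < 2:
        raise ValueError("2D-COS needs at least 2 spectra")
    idx = perturbation_order(spectra_set) if order is None else np.asarray(order, int)
    Y = spectra_set.matrix[idx]
    m = Y.shape[0]
    Yd = Y - Y.mean(axis=0)
    sync = Yd.T @ Yd / (m - 1)
    sync = (sync + sync.T) / 2.0
    async_ = Yd.T @ noda_matrix(m) @ Yd / (m - 1)
    async_ = (async_ - async_.T) / 2.0
    np.fill_diagonal(async_, 0.0)
    ordered_ids = [
        f"{spectra_set.meta.iloc[i]['donor_id']}:{spectra_set.meta.iloc[i]['replicate_id']}"
        for i in idx
    ]
    return CorrelationMaps(spectra_set.grid.copy(), sync, async_, ordered_ids)
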