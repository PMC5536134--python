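"""Clustering index: a Monte-Carlo nearest-neighbor-distance z-score.

For a 2D scatter of N points, let d0 be the mean nearest-neighbor
distance (NND). Under complete spatial randomness (CSR) the points would
spread uniformly over the region covering the data — here its axis-aligned
bounding box. The clustering index is

    z = (d0 - dE) / sigma

where dE and sigma are the mean and sample standard deviation of the mean
NND over ``n_sim`` uniform simulations of N points in the same box. A
strongly negative z means points sit closer together than CSR predicts
(clumping/clustering); z near 0 is CSR-like; positive z means
overdispersion. The simulation stream is a deterministic function of the
seed, and CSR points are drawn in unit coordinates and affinely mapped to
the box, so translating the data or scaling both axes by one factor leaves
z exactly unchanged for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, DimensionMismatchError, FvfcError
from .eigengene import EigengeneSet


@dataclass
class ClusteringIndexMatrix:
    """Symmetric z-score matrix over selected eigengene pairs; the diagonal
    is undefined and stored as NaN."""

    z: np.ndarray
    module_ids: list[int]
    n_simulations: int
    seed: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        L = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != L:
            raise DimensionMismatchError("z must be square")
        if len(self.module_ids) != L:
            raise DimensionMismatchError("module_ids length != z size")

    @property
    def n_modules(self) -> int:
        return self.z.shape[0]


def mean_nnd(points: np.ndarray) -> float:
    """Mean over all points of the Euclidean distance to the nearest other
    point. Duplicate locations give an NND of 0."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FvfcError("points must be an (n, 2) array")
    if pts.shape[0] < 2:
        raise FvfcError(f"need at least 2 points, got {pts.shape[0]}")
    dist, _ = cKDTree(pts).query(pts, k=2)
    return float(dist[:, 1].mean())


def _bounding_box(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bounding box (lo, extent); a flat dimension is inflated to 1e-9 of
    the other dimension's extent so the box keeps positive area."""
    lo = pts.min(axis=0)
    extent = pts.max(axis=0) - lo
    if extent[0] == 0 and extent[1] == 0:
        raise DegenerateInputError("all points identical: bounding box has no extent")
    for d in (0, 1):
        if extent[d] == 0:
            extent = extent.copy()
            extent[d] = 1e-9 * extent[1 - d]
    return lo, extent


def simulate_null_mean_nnds(
    n_points: int,
    lo: np.ndarray,
    extent: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean NND of ``n_sim`` uniform (CSR) samples of ``n_points`` in the box."""
    out = np.empty(n_sim)
    for s in range(n_sim):
        unit = rng.random((n_points, 2))
        out[s] = mean_nnd(lo + unit * extent)
    return out


def clustering_index(
    points: np.ndarray,
    n_sim: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """The NND z-score of a point set against its Monte-Carlo CSR null."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FvfcError("points must be an (n, 2) array")
    if pts.shape[0] < 2:
        raise FvfcError(f"need at least 2 points, got {pts.shape[0]}")
    if n_sim < 2:
        raise FvfcError("n_sim must be >= 2")
    lo, extent = _bounding_box(pts)
    d0 = mean_nnd(pts)
    rng = np.random.default_rng(seed)
    sims = simulate_null_mean_nnds(pts.shape[0], lo, extent, n_sim, rng)
    d_e = sims.mean()
    sigma = sims.std(ddof=1)
    if sigma == 0:
        raise DegenerateInputError("null simulations have zero spread")
    return float((d0 - d_e) / sigma)


def pair_seed(seed: int, id_i: int, id_j: int) -> np.random.SeedSequence:
    """Deterministic per-pair stream: SeedSequence(seed) spawned on the
    sorted module-ID pair. Keyed by module IDs, not positions, so adding an
    eigengene to the set does not perturb existing pairs' values."""
    a, b = sorted((int(id_i), int(id_j)))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(a, b))


def pairwise_clustering_indices(
    es: EigengeneSet,
    n_sim: int = 100,
    seed: int = 0,
) -> ClusteringIndexMatrix:
    """Clustering index for every unordered pair of selected eigengenes."""
    sel = es.selected_subset()
    L = sel.n_modules
    if L < 2:
        raise FvfcError(f"need at least 2 selected eigengenes, got {L}")
    z = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            pts = np.column_stack([sel.vectors[i], sel.vectors[j]])
            ss = pair_seed(seed, sel.module_ids[i], sel.module_ids[j])
            z[i, j] = z[j, i] = clustering_index(pts, n_sim=n_sim, seed=ss)
    return ClusteringIndexMatrix(
        z=z, module_ids=list(sel.module_ids), n_simulations=n_sim, seed=int(seed)
    )


def write_clustering_indices(cim: ClusteringIndexMatrix, path) -> None:
    """TSV matrix with module-ID labels; first line records n_sim and seed."""
    with open(path, "w") as fh:
        fh.write(f"# n_simulations={cim.n_simulations} seed={cim.seed}\n")
        fh.write("module_id\t" + "\t".join(map(str, cim.module_ids)) + "\n")
        for mid, row in zip(cim.module_ids, cim.z):
            cells = "\t".join("nan" if np.isnan(v) else f"{v:.17g}" for v in row)
            fh.write(f"{mid}\t{cells}\n")
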