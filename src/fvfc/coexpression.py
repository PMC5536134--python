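"""Spearman correlation networks and lmQCM quasi-clique module mining.

The network is built from absolute Spearman rank correlations (rank
correlation avoids the normality assumption Pearson carries for RNA-seq
levels); negative correlations enter via their magnitude since the miner
operates on nonnegative edge weights.

lmQCM (local maximum Quasi-Clique Merger) mines densely connected gene
modules from the weighted network:

1. edges whose weight is a local maximum (no heavier edge touches either
   endpoint) and at least ``gamma`` seed candidate modules;
2. each seed grows greedily, repeatedly adding the outside vertex with the
   largest total weight to the current members; a candidate is accepted
   only while its average weight to the members and the resulting module
   density ``2 * sum(weights) / (n * (n - 1))`` both stay at or above the
   adaptive threshold ``gamma * (1 - 1 / (2 * lambda_ * (n + t)))`` at the
   grown size (the per-candidate condition is what keeps weakly attached
   vertices out of an otherwise dense module; the density condition makes
   the advertised lower bound on returned-module density hold by
   construction);
3. modules smaller than ``min_size`` are dropped;
4. modules overlapping by ``|A & B| / min(|A|, |B|) >= beta`` are merged,
   largest first, to a fixed point.

``gamma`` is the single most consequential parameter: it is the minimum
weight of a module's first edge and so controls how many modules exist and
how large they grow. All tie-breaks use the smallest gene index, making the
output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ConstantGeneError, DimensionMismatchError, FvfcError
from .io import ExpressionMatrix


@dataclass
class CorrelationNetwork:
    """Symmetric nonnegative gene-gene weight matrix with a zeroed diagonal."""

    weights: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionMismatchError("weights must be square")
        if len(self.gene_ids) != w.shape[0]:
            raise DimensionMismatchError("gene_ids length != weight matrix size")
        if not np.allclose(w, w.T, atol=1e-12):
            raise FvfcError("weight matrix must be symmetric")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise FvfcError("off-diagonal weights must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]


@dataclass
class GeneModule:
    """An ordered set of member gene indices; modules may overlap."""

    module_id: int
    members: list[int]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise FvfcError(f"module {self.module_id}: duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)

    def gene_ids(self, all_gene_ids: list[str]) -> list[str]:
        return [all_gene_ids[i] for i in self.members]


def spearman_matrix(em: ExpressionMatrix) -> np.ndarray:
    """Pairwise Spearman rank correlation between all genes.

    Ranks use average-rank tie handling; the result is symmetric with a
    unit diagonal. Genes with zero variance are rejected because their
    rank correlation is undefined.
    """
    if em.n_cells < 3:
        raise FvfcError(f"need at least 3 cells, got {em.n_cells}")
    variances = em.values.var(axis=1)
    const = np.flatnonzero(variances == 0)
    if const.size:
        raise ConstantGeneError(
            f"constant gene(s): {[em.gene_ids[i] for i in const[:5]]}"
        )
    ranks = rankdata(em.values, axis=1)
    corr = np.corrcoef(ranks)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def to_network(
    corr: np.ndarray,
    gene_ids: list[str],
    normalize: bool = False,
) -> CorrelationNetwork:
    """Turn a correlation matrix into a mining network.

    Weights are absolute correlations with the diagonal zeroed. With
    ``normalize`` each weight w_ij is divided by sqrt(d_i * d_j), where d_i
    is gene i's row sum of weights, and the matrix is rescaled so its
    maximum weight is 1 (a symmetric degree normalization analogous to a
    normalized graph adjacency).
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise DimensionMismatchError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise FvfcError("correlation matrix must be symmetric")
    w = np.abs(corr).astype(float)
    np.fill_diagonal(w, 0.0)
    if normalize:
        d = w.sum(axis=1)
        d[d == 0] = 1.0
        w = w / np.sqrt(np.outer(d, d))
        w = (w + w.T) / 2.0
        mx = w.max()
        if mx > 0:
            w = w / mx
        np.fill_diagonal(w, 0.0)
    return CorrelationNetwork(weights=w, gene_ids=list(gene_ids))


def adaptive_density_threshold(gamma: float, n: int, lambda_: float, t: float) -> float:
    """Minimum density required of a module of size ``n``."""
    return gamma * (1.0 - 1.0 / (2.0 * lambda_ * (n + t)))


def module_density(weights: np.ndarray, members: list[int]) -> float:
    """2 * (sum of member pairwise weights) / (n * (n - 1))."""
    n = len(members)
    if n < 2:
        return 0.0
    sub = weights[np.ix_(members, members)]
    return float(sub.sum() / (n * (n - 1)))


def mine_modules(
    net: CorrelationNetwork,
    gamma: float,
    lambda_: float = 1.0,
    t: float = 1.0,
    beta: float = 0.4,
    min_size: int = 10,
) -> list[GeneModule]:
    """Run lmQCM on the network. Returns modules sorted by size descending,
    ties broken by smallest member index; a ``gamma`` above the maximum edge
    weight yields an empty list."""
    if not (0 < gamma <= 1):
        raise FvfcError("gamma must be in (0, 1]")
    if min_size < 2:
        raise FvfcError("min_size must be >= 2")
    w = net.weights
    m = net.n_genes

    # Seed edges: weight >= gamma and no strictly heavier edge at either end.
    row_max = w.max(axis=1) if m else np.array([])
    iu, ju = np.triu_indices(m, k=1)
    wts = w[iu, ju]
    ok = wts >= gamma
    iu, ju, wts = iu[ok], ju[ok], wts[ok]
    local_max = (wts >= row_max[iu]) & (wts >= row_max[ju])
    seeds = sorted(
        zip(wts[local_max], iu[local_max], ju[local_max]),
        key=lambda e: (-e[0], e[1], e[2]),
    )

    raw: list[list[int]] = []
    seen: set[frozenset[int]] = set()
    for _, u, v in seeds:
        members = _grow(w, int(u), int(v), gamma, lambda_, t)
        if len(members) < min_size:
            continue
        key = frozenset(members)
        if key not in seen:
            seen.add(key)
            raw.append(members)

    merged = _merge_overlapping(raw, beta)
    merged.sort(key=lambda mem: (-len(mem), min(mem)))
    return [GeneModule(module_id=k + 1, members=mem) for k, mem in enumerate(merged)]


def _grow(
    w: np.ndarray, u: int, v: int, gamma: float, lambda_: float, t: float
) -> list[int]:
    members = [u, v]
    in_mod = np.zeros(w.shape[0], dtype=bool)
    in_mod[[u, v]] = True
    contrib = w[:, u] + w[:, v]  # total weight of each vertex to members
    edge_sum = w[u, v]
    while True:
        cand_contrib = np.where(in_mod, -np.inf, contrib)
        cand = int(np.argmax(cand_contrib))  # argmax takes smallest index on ties
        if not np.isfinite(cand_contrib[cand]):
            break
        n = len(members)
        tau = adaptive_density_threshold(gamma, n + 1, lambda_, t)
        density = 2.0 * (edge_sum + contrib[cand]) / ((n + 1) * n)
        if contrib[cand] < n * tau or density < tau:
            break
        members.append(cand)
        in_mod[cand] = True
        edge_sum += contrib[cand]
        contrib = contrib + w[:, cand]
    return members


def _merge_overlapping(mods: list[list[int]], beta: float) -> list[list[int]]:
    mods = [list(m) for m in mods]
    changed = True
    while changed:
        changed = False
        mods.sort(key=lambda mem: (-len(mem), min(mem) if mem else 0))
        for a in range(len(mods)):
            for b in range(a + 1, len(mods)):
                sa, sb = set(mods[a]), set(mods[b])
                overlap = len(sa & sb) / min(len(sa), len(sb))
                if overlap >= beta:
                    extra = [g for g in mods[b] if g not in sa]
                    mods[a] = mods[a] + extra
                    del mods[b]
                    changed = True
                    break
            if changed:
                break
    return mods


def write_modules(
    modules: list[GeneModule], gene_ids: list[str], path
) -> None:
    """TSV with columns module_id, size, comma-separated gene IDs."""
    with open(path, "w") as fh:
        fh.write("module_id\tsize\tgenes\n")
        for mod in modules:
            fh.write(
                f"{mod.module_id}\t{mod.size}\t{','.join(mod.gene_ids(gene_ids))}\n"
            )
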