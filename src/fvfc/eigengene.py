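"""Module summarization: one sign-fixed eigengene per gene module.

The eigengene of a module is the first right singular vector of the
module's standardized expression submatrix (each gene row centered to mean
zero and scaled to unit Euclidean norm) — i.e. the first principal
component of the module across cells. Because a singular vector is defined
only up to sign, the sign is fixed so that the eigengene points along the
majority of its member genes: if the sum over genes of sgn(g_i . v1)
computed on the *raw* rows is negative, v1 is negated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    DimensionMismatchError,
    FvfcError,
    ZeroVarianceError,
)
from .io import ExpressionMatrix
from .coexpression import GeneModule


@dataclass
class EigengeneSet:
    """Eigengenes for a list of modules, one unit-norm row per module.

    ``kurtosis`` and ``selected`` start unset (NaN / all-True) and are
    populated by the distribution filter.
    """

    vectors: np.ndarray  # (L, N)
    module_ids: list[int]
    kurtosis: np.ndarray = field(default=None)  # type: ignore[assignment]
    selected: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        L = self.vectors.shape[0]
        if len(self.module_ids) != L:
            raise DimensionMismatchError("module_ids length != number of eigengenes")
        if self.kurtosis is None:
            self.kurtosis = np.full(L, np.nan)
        if self.selected is None:
            self.selected = np.ones(L, dtype=bool)
        self.kurtosis = np.asarray(self.kurtosis, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.kurtosis.shape != (L,) or self.selected.shape != (L,):
            raise DimensionMismatchError("kurtosis/selected length != number of eigengenes")
        norms = np.linalg.norm(self.vectors, axis=1)
        if L and not np.allclose(norms, 1.0, atol=1e-9):
            raise FvfcError("every eigengene must have unit norm")

    @property
    def n_modules(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_cells(self) -> int:
        return self.vectors.shape[1]

    def selected_subset(self) -> "EigengeneSet":
        """The selected eigengenes only, order preserved."""
        idx = np.flatnonzero(self.selected)
        return EigengeneSet(
            vectors=self.vectors[idx],
            module_ids=[self.module_ids[i] for i in idx],
            kurtosis=self.kurtosis[idx],
            selected=self.selected[idx],
            cell_ids=list(self.cell_ids) if self.cell_ids else None,
        )

    def row_for_module(self, module_id: int) -> int:
        try:
            return self.module_ids.index(module_id)
        except ValueError:
            raise FvfcError(f"no eigengene for module {module_id}") from None


def standardize_rows(sub: np.ndarray) -> np.ndarray:
    """Center each row to mean 0 and scale to Euclidean norm 1."""
    sub = np.atleast_2d(np.asarray(sub, dtype=float))
    centered = sub - sub.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ZeroVarianceError(f"zero-variance row(s) at index {zero.tolist()[:5]}")
    return centered / norms[:, None]


def compute_eigengene(sub: np.ndarray) -> np.ndarray:
    """Eigengene of a raw module submatrix (genes x cells).

    Standardizes the rows, takes the first right singular vector, and
    applies the majority-sign rule against the raw rows. A tie in the sign
    sum leaves the vector unflipped. Deterministic: LAPACK SVD, no
    randomized solver.
    """
    sub = np.atleast_2d(np.asarray(sub, dtype=float))
    std = standardize_rows(sub)
    _, s, vt = np.linalg.svd(std, full_matrices=False)
    if s[0] <= 0:
        raise DegenerateInputError("module submatrix is zero after standardization")
    v1 = vt[0]
    if np.sum(np.sign(sub @ v1)) < 0:
        v1 = -v1
    return v1


def eigengenes_for_modules(
    em: ExpressionMatrix, modules: list[GeneModule]
) -> EigengeneSet:
    """One eigengene per module, rows in module-list order."""
    vectors = np.empty((len(modules), em.n_cells))
    for k, mod in enumerate(modules):
        bad = [i for i in mod.members if i < 0 or i >= em.n_genes]
        if bad:
            raise FvfcError(
                f"module {mod.module_id} references gene index {bad[0]} "
                f"outside the {em.n_genes}-gene matrix (filtered out?)"
            )
        vectors[k] = compute_eigengene(em.values[mod.members])
    return EigengeneSet(
        vectors=vectors,
        module_ids=[m.module_id for m in modules],
        cell_ids=list(em.cell_ids),
    )


def write_eigengenes(es: EigengeneSet, path) -> None:
    """TSV: one row per module, columns are cell IDs."""
    cells = es.cell_ids or [f"cell{i + 1}" for i in range(es.n_cells)]
    with open(path, "w") as fh:
        fh.write("module_id\t" + "\t".join(cells) + "\n")
        for mid, row in zip(es.module_ids, es.vectors):
            fh.write(str(mid) + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
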