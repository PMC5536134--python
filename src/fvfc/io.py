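"""Expression-matrix input/output and gene-level preprocessing.

The on-disk dialects are deliberately plain:

* dense TSV/CSV — one row per gene, gene IDs in the first column, a header
  row of cell IDs;
* sparse Matrix Market (``.mtx``, coordinate format, 1-based) with
  one-column gene-ID and cell-ID sidecar text files;
* annotations — a two-column table mapping cell ID to a categorical label.

Gene filtering implements the two rules used when preparing single-cell
matrices for coexpression mining: drop genes that are zero in more than a
given fraction of cells (dropout-dominated genes), then drop genes that sit
simultaneously in the lowest quantiles of both mean and variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    AnnotationConflictError,
    DimensionMismatchError,
    DuplicateIDError,
    EmptyResultError,
    FvfcError,
    MalformedHeaderError,
)

_DELIMS = {"dense-tsv": "\t", "dense-csv": ","}


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with string identifiers.

    Parameters
    ----------
    values : ndarray of shape (M, N)
        Expression levels (library-normalized or log-scale, as provided).
    gene_ids : list of str
        M unique gene identifiers (rows).
    cell_ids : list of str
        N unique cell identifiers (columns).
    annotations : dict, optional
        Map from cell ID to a categorical label. Keys must be existing
        cell IDs; cells absent from the map are treated as "unlabeled".
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    annotations: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DimensionMismatchError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DimensionMismatchError(
                f"values has shape {self.values.shape} but there are "
                f"{len(self.gene_ids)} gene IDs and {len(self.cell_ids)} cell IDs"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.annotations is not None:
            unknown = set(self.annotations) - set(self.cell_ids)
            if unknown:
                raise FvfcError(
                    f"annotation keys are not cell IDs: {sorted(unknown)[:5]}"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``keep`` (bool mask or indices),
        preserving gene order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            values=self.values[keep].copy(),
            gene_ids=[self.gene_ids[i] for i in keep],
            cell_ids=list(self.cell_ids),
            annotations=dict(self.annotations) if self.annotations else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def _check_unique(ids: list[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise DuplicateIDError(f"duplicate {kind} IDs: {dups[:5]}")


def read_expression(
    path: str | Path,
    format: str = "dense-tsv",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``format`` is one of ``dense-tsv``, ``dense-csv`` or ``mtx``. The dense
    dialect is chosen by the flag alone (no sniffing) and requires gene IDs
    in the first column under a header row of cell IDs. For ``mtx`` the
    gene/cell sidecars default to ``<path>.genes.txt`` / ``<path>.cells.txt``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in _DELIMS:
        return _read_dense(path, _DELIMS[format])
    if format == "mtx":
        return _read_mtx(path, genes_path, cells_path)
    raise FvfcError(f"unknown format {format!r}")


def _read_dense(path: Path, delim: str) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    if not header:
        raise MalformedHeaderError(f"{path}: empty header line")
    cols = header.split(delim)
    if len(cols) < 2:
        raise MalformedHeaderError(
            f"{path}: header has no cell ID columns (delimiter {delim!r})"
        )
    cell_ids = cols[1:]
    if any(c == "" for c in cell_ids):
        raise MalformedHeaderError(f"{path}: blank cell ID in header")
    _check_unique(cell_ids, "cell")
    df = pd.read_csv(path, sep=delim, header=0, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    _check_unique(gene_ids, "gene")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FvfcError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids)


def _read_mtx(
    path: Path,
    genes_path: str | Path | None,
    cells_path: str | Path | None,
) -> ExpressionMatrix:
    genes_path = Path(genes_path) if genes_path else path.with_suffix(path.suffix + ".genes.txt")
    cells_path = Path(cells_path) if cells_path else path.with_suffix(path.suffix + ".cells.txt")
    for p in (genes_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(f"missing MTX sidecar {p}")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    gene_ids = genes_path.read_text().split()
    cell_ids = cells_path.read_text().split()
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise DimensionMismatchError(
            f"MTX is {mat.shape} but sidecars list {len(gene_ids)} genes "
            f"and {len(cell_ids)} cells"
        )
    return ExpressionMatrix(values=mat, gene_ids=gene_ids, cell_ids=cell_ids)


def write_expression(em: ExpressionMatrix, path: str | Path, format: str = "dense-tsv") -> Path:
    """Write a dense TSV/CSV that :func:`read_expression` round-trips
    bit-exactly (floats are printed with 17 significant digits)."""
    path = Path(path)
    if format not in _DELIMS:
        raise FvfcError(f"unknown dense format {format!r}")
    delim = _DELIMS[format]
    with open(path, "w") as fh:
        fh.write("gene" + delim + delim.join(em.cell_ids) + "\n")
        for gid, row in zip(em.gene_ids, em.values):
            fh.write(gid + delim + delim.join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_annotations(path: str | Path, has_header: bool = False) -> dict[str, str]:
    """Read a two-column (cell ID, label) TSV into a dict.

    An empty file yields an empty map. A cell ID repeated with conflicting
    labels raises :class:`AnnotationConflictError`; consistent repeats are
    tolerated.
    """
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if lineno == 0 and has_header:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FvfcError(f"{path}:{lineno + 1}: expected 2 columns, got {len(parts)}")
            cell, label = parts
            if cell in out and out[cell] != label:
                raise AnnotationConflictError(
                    f"{path}: cell {cell!r} labeled both {out[cell]!r} and {label!r}"
                )
            out[cell] = label
    return out


def write_annotations(annotations: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for cell, label in annotations.items():
            fh.write(f"{cell}\t{label}\n")
    return path


def filter_genes(
    em: ExpressionMatrix,
    max_zero_fraction: float = 0.5,
    mean_lowest_pct: float = 0.2,
    var_lowest_pct: float = 0.5,
    combine: str = "and",
) -> ExpressionMatrix:
    """Apply the two gene-level preprocessing filters.

    First remove genes whose zero count strictly exceeds
    ``max_zero_fraction * N``. Then, among the survivors, remove genes that
    fall in the lowest ``mean_lowest_pct`` quantile of means *and* (with
    ``combine="or"``, *or*) the lowest ``var_lowest_pct`` quantile of
    variances. Quantile cutoffs use the nearest-rank definition on the
    post-zero-filter gene set; genes tied at the cutoff value are removed
    (the lower tail is inclusive). Gene order is otherwise preserved and the
    input is not modified.
    """
    if em.n_genes == 0:
        raise EmptyResultError("input matrix has no genes")
    if combine not in ("and", "or"):
        raise FvfcError(f"combine must be 'and' or 'or', got {combine!r}")
    n = em.n_cells
    zero_counts = (em.values == 0).sum(axis=1)
    pass_zero = zero_counts <= max_zero_fraction * n
    n_zero_removed = int((~pass_zero).sum())

    surv = em.values[pass_zero]
    means = surv.mean(axis=1)
    variances = surv.var(axis=1)
    low_mean = _lowest_tail(means, mean_lowest_pct)
    low_var = _lowest_tail(variances, var_lowest_pct)
    low_both = (low_mean & low_var) if combine == "and" else (low_mean | low_var)
    n_quant_removed = int(low_both.sum())

    keep = np.flatnonzero(pass_zero)[~low_both]
    if keep.size == 0:
        raise EmptyResultError(
            f"all {em.n_genes} genes removed "
            f"(zero-fraction rule: {n_zero_removed}, quantile rule: {n_quant_removed})"
        )
    return em.subset_genes(keep)


def _lowest_tail(x: np.ndarray, pct: float) -> np.ndarray:
    """Boolean mask of values in the lowest ``pct`` quantile, nearest-rank,
    inclusive of ties at the cutoff."""
    m = x.size
    k = math.ceil(pct * m)
    if k <= 0:
        return np.zeros(m, dtype=bool)
    cutoff = np.sort(x, kind="stable")[k - 1]
    return x <= cutoff
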