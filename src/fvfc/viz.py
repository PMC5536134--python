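"""SPLOM rendering, annotated pair scatters, and the 3D PCA comparison plot.

The scatter-plot matrix (SPLOM) puts eigengene i against eigengene j in
panel (i, j), histograms on the diagonal, and colors each off-diagonal
panel's background by the pair's clustering index through a diverging
colormap centered at z = 0 — the most negative panels (strongest clumping)
stand out at one end of the scale. Point colors stay free for cell
annotations, which is why the index is encoded in the panel background
rather than the points.

Static output is PNG or SVG (matplotlib, rendered deterministically so the
same inputs give byte-identical SVG); ``.html`` output embeds the figure in
a self-contained page, and pair scatters written as HTML carry per-point
hover tooltips with the cell IDs.
"""

from __future__ import annotations

import html
from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib import colors as mcolors
from matplotlib import cm
from sklearn.decomposition import PCA

from .errors import (
    DegenerateInputError,
    DimensionMismatchError,
    FvfcError,
    UnknownModuleError,
)
from .eigengene import EigengeneSet
from .io import ExpressionMatrix
from .spatial import ClusteringIndexMatrix

_EXTS = (".png", ".svg", ".html")
_CMAP = "coolwarm"  # diverging, monotone in z
_UNLABELED = "unlabeled"
# deterministic SVG: fixed hash salt, no embedded creation date
_SVG_OPTS = {"metadata": {"Date": None}}


def _check_ext(out: str | Path) -> str:
    ext = Path(out).suffix.lower()
    if ext not in _EXTS:
        raise FvfcError(f"unsupported output extension {ext!r}; use one of {_EXTS}")
    return ext


def _z_norm(z: np.ndarray) -> mcolors.Normalize:
    finite = z[np.isfinite(z)]
    vmax = float(np.abs(finite).max()) if finite.size else 1.0
    vmax = max(vmax, 1e-12)
    return mcolors.Normalize(vmin=-vmax, vmax=vmax)


def _save(fig, out: Path, ext: str) -> Path:
    with matplotlib.rc_context({"svg.hashsalt": "fvfc"}):
        if ext == ".html":
            import io as _io

            buf = _io.StringIO()
            fig.savefig(buf, format="svg", **_SVG_OPTS)
            out.write_text(_wrap_html(buf.getvalue()))
        elif ext == ".svg":
            fig.savefig(out, format="svg", **_SVG_OPTS)
        else:
            fig.savefig(out, format="png", dpi=150)
    plt.close(fig)
    return out


def _wrap_html(svg: str) -> str:
    body = svg[svg.index("<svg") :] if "<svg" in svg else svg
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>fvfc</title></head>\n<body>\n" + body + "\n</body></html>\n"
    )


def build_splom_figure(
    es: EigengeneSet, cim: ClusteringIndexMatrix, bins: int = 30
):
    """The SPLOM figure for the *selected* eigengenes of ``es``; exposed
    separately from :func:`render_splom` so panel layout is testable."""
    sel = es.selected_subset()
    L = sel.n_modules
    if L < 2:
        raise FvfcError("SPLOM needs at least 2 selected eigengenes")
    if list(cim.module_ids) != list(sel.module_ids) or cim.n_modules != L:
        raise DimensionMismatchError(
            "clustering-index matrix does not match the selected eigengenes"
        )
    norm = _z_norm(cim.z)
    cmap = plt.get_cmap(_CMAP)
    fig, axes = plt.subplots(L, L, figsize=(2.0 * L + 1.5, 2.0 * L))
    axes = np.atleast_2d(axes)
    for i in range(L):
        for j in range(L):
            ax = axes[i, j]
            if i == j:
                ax.hist(sel.vectors[i], bins=bins, color="0.35")
            else:
                ax.set_facecolor(cmap(norm(cim.z[i, j])))
                ax.scatter(sel.vectors[j], sel.vectors[i], s=3, c="k", linewidths=0)
            ax.set_xticks([])
            ax.set_yticks([])
            if i == L - 1:
                ax.set_xlabel(f"#{sel.module_ids[j]}", fontsize=8)
            if j == 0:
                ax.set_ylabel(f"#{sel.module_ids[i]}", fontsize=8)
    sm = cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=axes, label="clustering index z", shrink=0.7)
    return fig


def render_splom(
    es: EigengeneSet,
    cim: ClusteringIndexMatrix,
    out: str | Path,
    bins: int = 30,
) -> Path:
    """Render the clustering-index-colored SPLOM to PNG/SVG/HTML."""
    out = Path(out)
    ext = _check_ext(out)
    fig = build_splom_figure(es, cim, bins=bins)
    return _save(fig, out, ext)


def _point_colors(
    cell_ids: list[str] | None,
    n: int,
    annotations: dict[str, str] | None,
):
    """Per-point colors and a label -> color legend map."""
    if annotations is None:
        return ["C0"] * n, {}
    cells = cell_ids or [str(i) for i in range(n)]
    labels = sorted({annotations[c] for c in cells if c in annotations})
    cmap = plt.get_cmap("tab10")
    lut = {lab: mcolors.to_hex(cmap(k % 10)) for k, lab in enumerate(labels)}
    colors = [lut.get(annotations.get(c, _UNLABELED), "0.6") for c in cells]
    return colors, lut


def render_pair(
    es: EigengeneSet,
    i: int,
    j: int,
    annotations: dict[str, str] | None = None,
    out: str | Path = "pair.png",
) -> Path:
    """Scatter of eigengene ``i`` (x) against ``j`` (y), by module ID.

    With annotations, points are colored by label (unlabeled cells gray)
    and a legend is drawn. HTML output is a self-contained page whose
    points show the cell ID on hover.
    """
    out = Path(out)
    ext = _check_ext(out)
    if i == j:
        raise FvfcError("pair plot needs two distinct eigengenes")
    for mid in (i, j):
        if mid not in es.module_ids:
            raise UnknownModuleError(f"no eigengene for module {mid}")
        if not es.selected[es.row_for_module(mid)]:
            raise FvfcError(f"eigengene for module {mid} is not selected")
    x = es.vectors[es.row_for_module(i)]
    y = es.vectors[es.row_for_module(j)]
    colors, lut = _point_colors(es.cell_ids, x.size, annotations)

    if ext == ".html":
        out.write_text(_hover_scatter_html(x, y, es.cell_ids, colors, lut, i, j))
        return out

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=8, c=colors, linewidths=0)
    ax.set_xlabel(f"eigengene #{i}")
    ax.set_ylabel(f"eigengene #{j}")
    if lut:
        handles = [
            plt.Line2D([], [], marker="o", ls="", color=c, label=lab)
            for lab, c in lut.items()
        ]
        ax.legend(handles=handles, fontsize=8, loc="best")
    return _save(fig, out, ext)


def _hover_scatter_html(
    x: np.ndarray,
    y: np.ndarray,
    cell_ids: list[str] | None,
    colors: list[str],
    lut: dict[str, str],
    mid_x: int,
    mid_y: int,
) -> str:
    """Hand-written SVG scatter with <title> hover tooltips, wrapped in HTML."""
    cells = cell_ids or [str(k) for k in range(x.size)]
    w = h = 480
    pad = 30
    lox, hix = float(x.min()), float(x.max())
    loy, hiy = float(y.min()), float(y.max())
    sx = (w - 2 * pad) / (hix - lox if hix > lox else 1.0)
    sy = (h - 2 * pad) / (hiy - loy if hiy > loy else 1.0)
    circles = []
    for xi, yi, cid, col in zip(x, y, cells, colors):
        px = pad + (xi - lox) * sx
        py = h - pad - (yi - loy) * sy
        col_hex = mcolors.to_hex(col)
        circles.append(
            f"<circle cx='{px:.2f}' cy='{py:.2f}' r='3' fill='{col_hex}'>"
            f"<title>{html.escape(cid)}</title></circle>"
        )
    legend = "".join(
        f"<div><span style='color:{c}'>&#9679;</span> {html.escape(lab)}</div>"
        for lab, c in lut.items()
    )
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>eigengene #{mid_x} vs #{mid_y}</title></head>\n<body>\n"
        f"<h3>eigengene #{mid_x} (x) vs eigengene #{mid_y} (y)</h3>\n"
        f"<svg width='{w}' height='{h}' xmlns='http://www.w3.org/2000/svg'>"
        f"<rect width='{w}' height='{h}' fill='white' stroke='black'/>"
        + "".join(circles)
        + "</svg>\n"
        + legend
        + "\n</body></html>\n"
    )


def pca_cells_3d(
    em: ExpressionMatrix,
    gene_subset: list[str] | None = None,
    color_groups: dict[str, str] | None = None,
    out: str | Path = "pca.png",
) -> Path:
    """Project cells on the top three principal components of the expression
    matrix (cells as observations, genes as features) and render a 3D
    scatter, optionally colored by group label."""
    out = Path(out)
    ext = _check_ext(out)
    if gene_subset is not None:
        idx = [k for k, g in enumerate(em.gene_ids) if g in set(gene_subset)]
        if not idx:
            raise FvfcError("gene subset matches no genes in the matrix")
        em = em.subset_genes(np.asarray(idx))
    if em.n_genes < 3 or em.n_cells < 3:
        raise FvfcError("PCA needs at least 3 genes and 3 cells")
    X = em.values.T  # cells x genes
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateInputError("all cells identical: PCA is undefined")
    coords = PCA(n_components=3, svd_solver="full").fit_transform(X)
    colors, lut = _point_colors(em.cell_ids, em.n_cells, color_groups)
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(coords[:, 0], coords[:, 1], coords[:, 2], s=8, c=colors)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    if lut:
        handles = [
            plt.Line2D([], [], marker="o", ls="", color=c, label=lab)
            for lab, c in lut.items()
        ]
        ax.legend(handles=handles, fontsize=8)
    return _save(fig, out, ext)
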