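"""Kurtosis-based selection of informative eigengenes.

An eigengene is worth plotting when its distribution over cells is bimodal
or long-tailed — those are the ones that split the cell population. A
narrow sharp-peaked unimodal distribution carries little separation signal
and shows up as *large* kurtosis (a normal distribution sits at 3; values
well above that indicate a sharp peak with heavy concentration, while a
symmetric two-point distribution — the extreme bimodal case — sits at the
theoretical minimum of 1). Eigengenes with kurtosis strictly below a
user-chosen threshold are kept.
"""

from __future__ import annotations

import numpy as np

from .errors import FvfcError, ZeroVarianceError
from .eigengene import EigengeneSet


def kurtosis(w: np.ndarray) -> float:
    """Population (non-excess) kurtosis E[(w - mu)^4] / E[(w - mu)^2]^2.

    Moments divide by N with no bias correction, so normal data gives
    about 3. Invariant to affine maps a*w + b (a != 0), and >= 1 for any
    nondegenerate input.
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.size < 4:
        raise FvfcError(f"kurtosis needs at least 4 values, got {w.size}")
    centered = w - w.mean()
    m2 = np.mean(centered**2)
    if m2 == 0:
        raise ZeroVarianceError("kurtosis undefined for zero-variance input")
    return float(np.mean(centered**4) / m2**2)


def select_informative(es: EigengeneSet, threshold: float) -> EigengeneSet:
    """Populate kurtosis for every eigengene and flag as selected those with
    kurtosis strictly below ``threshold``. Returns a new set; rows are not
    dropped (use :meth:`EigengeneSet.selected_subset` for that)."""
    kurt = np.array([kurtosis(row) for row in es.vectors])
    return EigengeneSet(
        vectors=es.vectors.copy(),
        module_ids=list(es.module_ids),
        kurtosis=kurt,
        selected=kurt < threshold,
        cell_ids=list(es.cell_ids) if es.cell_ids else None,
    )


def write_selection_report(es: EigengeneSet, module_sizes: dict[int, int], path) -> None:
    """TSV with module_id, size, kurtosis, selected."""
    with open(path, "w") as fh:
        fh.write("module_id\tsize\tkurtosis\tselected\n")
        for mid, k, sel in zip(es.module_ids, es.kurtosis, es.selected):
            size = module_sizes.get(mid, -1)
            fh.write(f"{mid}\t{size}\t{k:.6g}\t{bool(sel)}\n")
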