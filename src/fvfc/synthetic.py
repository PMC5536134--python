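"""Synthetic expression matrices with planted coexpression structure.

The generator emulates the features of processed single-cell expression
data that the pipeline exploits, without pretending to be a count model:

* planted gene modules — each module's genes share a latent per-cell factor
  plus independent Gaussian noise scaled so that any two member genes show
  approximately ``within_corr`` Spearman correlation (the correlation the
  downstream network actually uses; the noise scale is calibrated by
  bisection against a fixed probe-noise draw, so it is deterministic and
  holds for non-Gaussian factors too);
* cell subpopulations — the latent factor is shifted by ``group_shift`` per
  cell group, so a module with two groups produces a bimodal eigengene;
* a sharp-peaked control — a module whose latent factor is a narrow
  Gaussian with a small heavy-tail admixture (``factor_dist="sharp"``) has
  a single sharp-peaked mode and high kurtosis, which the distribution
  filter should reject; ``"laplace"`` gives a milder heavy-centered control;
* background genes of pure independent noise;
* dropout — entries zeroed uniformly at random at ``dropout_rate``.
  Dropout zeros attenuate rank correlations below the calibrated target,
  exactly as they would in real processed data.

Everything is reproducible from the spec's seed. Modules that share a
``group_key`` share the same cell-group partition (their eigengene pair
scatters into coincident clumps); modules without a key get independent
partitions.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FvfcError
from .io import ExpressionMatrix, write_annotations, write_expression


@dataclass
class ModuleSpec:
    """One planted coexpression module.

    ``n_cell_groups`` latent-factor modes separated by ``group_shift``
    (in units of the factor's unit base spread); ``factor_dist`` is
    ``"normal"``, ``"laplace"`` or ``"sharp"`` (the last is a narrow peak
    with a heavy-tail admixture — a high-kurtosis control).
    """

    size: int
    n_cell_groups: int = 1
    group_shift: float = 0.0
    within_corr: float = 0.8
    factor_dist: str = "normal"
    group_key: str | None = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise FvfcError("module size must be positive")
        if self.n_cell_groups < 1:
            raise FvfcError("n_cell_groups must be >= 1")
        if not (0 < self.within_corr < 1):
            raise FvfcError(
                f"within_corr must be strictly between 0 and 1, got {self.within_corr}"
            )
        if self.factor_dist not in ("normal", "laplace", "sharp"):
            raise FvfcError(f"unknown factor_dist {self.factor_dist!r}")


@dataclass
class SyntheticSpec:
    """Full synthetic-dataset description; ``generate`` is deterministic in
    ``seed``."""

    n_cells: int
    n_background_genes: int
    modules: list[ModuleSpec]
    dropout_rate: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_background_genes < 0:
            raise FvfcError("sizes must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise FvfcError("dropout_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise FvfcError("noise_sd must be > 0")


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The study conditions used throughout the test bench: 500 cells, three
    planted modules of 20 genes at within-module correlation 0.8 — two
    bimodal (two cell groups each, independent partitions) and one
    sharp-peaked control — over 200 background genes with 10% dropout."""
    return SyntheticSpec(
        n_cells=500,
        n_background_genes=200,
        modules=[
            ModuleSpec(size=20, n_cell_groups=2, group_shift=4.0,
                       within_corr=0.8),
            ModuleSpec(size=20, n_cell_groups=2, group_shift=4.0,
                       within_corr=0.8),
            ModuleSpec(size=20, n_cell_groups=1, group_shift=0.0,
                       within_corr=0.8, factor_dist="sharp"),
        ],
        dropout_rate=0.1,
        noise_sd=1.0,
        seed=seed,
    )


_BASELINE = 5.0  # keeps honest expression away from 0 so zeros mean dropout


def _group_assignment(spec: SyntheticSpec, mod: ModuleSpec, index: int) -> np.ndarray:
    """Cell-group labels for one module. Modules sharing a group_key share
    the partition; keyless modules get an independent one."""
    if mod.group_key is not None:
        entropy = (spec.seed, zlib.crc32(mod.group_key.encode()))
    else:
        entropy = (spec.seed, 2**31 + index)
    rng = np.random.default_rng(np.random.SeedSequence(entropy))
    return rng.integers(0, mod.n_cell_groups, size=spec.n_cells)


def _draw_base(rng: np.random.Generator, dist: str, n: int) -> np.ndarray:
    """Unit-variance latent base draw."""
    if dist == "laplace":
        return rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=n)
    if dist == "sharp":
        # 90% narrow peak, 10% five-fold-wider tail; unit total variance,
        # population kurtosis about 16 -- a "narrow sharp peak" shape
        w = 1.0 / np.sqrt(0.9 + 0.1 * 25.0)
        wide = rng.random(n) < 0.1
        return np.where(wide, 5.0 * w, w) * rng.standard_normal(n)
    return rng.standard_normal(n)


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _noise_sd_for_spearman(
    factor: np.ndarray,
    target: float,
    rng: np.random.Generator,
    n_probe: int = 8,
    n_iter: int = 40,
) -> float:
    """Noise standard deviation such that two genes built as
    ``factor + sd * noise`` have Spearman correlation ~= ``target``.

    The probe noise is drawn once and rescaled, so the probed correlation is
    exactly monotone in ``sd`` and plain bisection converges; the result is
    a deterministic function of the factor and the generator state.
    """
    n = factor.size
    probes = rng.standard_normal((n_probe, 2, n))

    def probed(sd: float) -> float:
        return float(
            np.mean(
                [_spearman_pair(factor + sd * e[0], factor + sd * e[1]) for e in probes]
            )
        )

    s = float(factor.std())
    lo, hi = 1e-6 * s, 100.0 * s
    for _ in range(n_iter):
        mid = np.sqrt(lo * hi)
        if probed(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, dict]:
    """Generate the matrix and its ground truth.

    Returns ``(em, truth)`` where ``truth`` has ``modules`` (name -> member
    gene IDs), ``cell_groups`` (name -> per-cell group index) and
    ``factors`` (name -> the latent factor each module's genes share).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_cells
    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth: dict = {"modules": {}, "cell_groups": {}, "factors": {}}

    for k, mod in enumerate(spec.modules):
        name = f"M{k + 1}"
        groups = _group_assignment(spec, mod, k)
        base = _draw_base(rng, mod.factor_dist, n)
        offsets = (groups - groups.mean()) * mod.group_shift
        factor = base + offsets
        if factor.var() == 0:
            raise FvfcError(f"module {name}: latent factor is constant")
        noise_sd = _noise_sd_for_spearman(factor, mod.within_corr, rng)
        ids = [f"{name}_G{j + 1}" for j in range(mod.size)]
        for gid in ids:
            rows.append(_BASELINE + factor + noise_sd * rng.standard_normal(n))
            gene_ids.append(gid)
        truth["modules"][name] = ids
        truth["cell_groups"][name] = groups.tolist()
        truth["factors"][name] = factor.tolist()

    for j in range(spec.n_background_genes):
        rows.append(_BASELINE + spec.noise_sd * rng.standard_normal(n))
        gene_ids.append(f"BG_G{j + 1}")

    values = np.vstack(rows) if rows else np.empty((0, n))
    if spec.dropout_rate > 0:
        mask = rng.random(values.shape) < spec.dropout_rate
        values = np.where(mask, 0.0, values)

    cell_ids = [f"CELL_{i + 1:04d}" for i in range(n)]
    em = ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids)
    return em, truth


def write_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path,
    annotate_module: str | None = None,
) -> dict[str, Path]:
    """Write matrix TSV, optional annotation TSV (cell groups of one module)
    and the ground-truth JSON sidecar; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    em, truth = generate(spec)
    paths = {"expression": out_dir / "expression.tsv", "truth": out_dir / "truth.json"}
    write_expression(em, paths["expression"], "dense-tsv")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    if annotate_module is not None:
        if annotate_module not in truth["cell_groups"]:
            raise FvfcError(f"no planted module named {annotate_module!r}")
        labels = {
            cell: f"group{g}"
            for cell, g in zip(em.cell_ids, truth["cell_groups"][annotate_module])
        }
        paths["annotations"] = out_dir / "annotations.tsv"
        write_annotations(labels, paths["annotations"])
    return paths
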