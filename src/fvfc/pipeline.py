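"""End-to-end orchestration of the three-stage workflow.

Stage 1 mines coexpression modules and summarizes each as an eigengene;
stage 2 keeps the informative (bimodal / long-tail) eigengenes and scores
every pair's scatter with the Monte-Carlo clustering index; stage 3 renders
the colored SPLOM. Every intermediate artifact is written to the run
directory, all randomness flows from the single configured seed, and a
manifest ties artifacts to the exact parameters used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import coexpression, eigengene, filtering, spatial, synthetic, viz
from .errors import StageError
from .io import ExpressionMatrix, filter_genes, read_annotations, read_expression

log = logging.getLogger("fvfc")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run. Either ``input_path`` or
    ``synthetic_spec`` must be provided."""

    input_path: str | None = None
    input_format: str = "dense-tsv"
    annotations_path: str | None = None
    synthetic_spec: synthetic.SyntheticSpec | None = None
    out_dir: str = "fvfc_run"
    # gene filtering
    max_zero_fraction: float = 0.5
    mean_lowest_pct: float = 0.2
    var_lowest_pct: float = 0.5
    # mining
    gamma: float = 0.75
    lambda_: float = 1.0
    t: float = 1.0
    beta: float = 0.4
    min_module_size: int = 10
    normalize_weights: bool = False
    # selection
    kurtosis_threshold: float = 20.0
    # spatial
    n_sims: int = 100
    seed: int = 0
    # viz
    bins: int = 30
    splom_format: str = "png"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic_spec is not None:
            d["synthetic_spec"] = dataclasses.asdict(self.synthetic_spec)
        return d


@dataclass
class PipelineResult:
    """Artifacts and in-memory products of a run."""

    run_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    expression: ExpressionMatrix | None = None
    modules: list = field(default_factory=list)
    eigengenes: eigengene.EigengeneSet | None = None
    clustering: spatial.ClusteringIndexMatrix | None = None


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s ...", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute filter -> correlate -> mine -> eigengenes -> select -> index
    -> SPLOM, writing each intermediate artifact. A stage failure raises
    :class:`StageError` naming the stage; artifacts written before the
    failure are retained."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(run_dir=run_dir)

    fh = logging.FileHandler(run_dir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        _run_stages(config, res)
    finally:
        _write_manifest(config, res)
        log.removeHandler(fh)
        fh.close()
    return res


def _run_stages(config: PipelineConfig, res: PipelineResult) -> None:
    em = _load(config)
    log.info("input: %d genes x %d cells", em.n_genes, em.n_cells)

    em = _filter(config, em)
    log.info("genes surviving filters: %d", em.n_genes)
    from .io import write_expression

    res.artifacts["filtered_expression"] = res.run_dir / "filtered_expression.tsv"
    write_expression(em, res.artifacts["filtered_expression"])
    res.expression = em

    modules = _mine(config, em)
    log.info("modules found: %d (min size %d)", len(modules), config.min_module_size)
    res.artifacts["modules"] = res.run_dir / "modules.tsv"
    coexpression.write_modules(modules, em.gene_ids, res.artifacts["modules"])
    res.modules = modules
    if not modules:
        log.info("no modules at gamma=%.3g; stopping after mining", config.gamma)
        return

    es = _eigengenes(em, modules)
    res.artifacts["eigengenes"] = res.run_dir / "eigengenes.tsv"
    eigengene.write_eigengenes(es, res.artifacts["eigengenes"])

    es = _select(config, es)
    n_sel = int(es.selected.sum())
    log.info(
        "eigengenes selected: %d of %d (kurtosis < %g)",
        n_sel, es.n_modules, config.kurtosis_threshold,
    )
    res.artifacts["selection"] = res.run_dir / "selection.tsv"
    filtering.write_selection_report(
        es, {m.module_id: m.size for m in modules}, res.artifacts["selection"]
    )
    res.eigengenes = es
    if n_sel < 2:
        log.info("fewer than 2 selected eigengenes; stopping before spatial scoring")
        return

    cim = _index(config, es)
    res.artifacts["clustering_index"] = res.run_dir / "clustering_index.tsv"
    spatial.write_clustering_indices(cim, res.artifacts["clustering_index"])
    res.clustering = cim

    res.artifacts["splom"] = res.run_dir / f"splom.{config.splom_format}"
    _splom(config, es, cim, res.artifacts["splom"])


@_stage("load")
def _load(config: PipelineConfig) -> ExpressionMatrix:
    if (config.input_path is None) == (config.synthetic_spec is None):
        raise ValueError("provide exactly one of input_path or synthetic_spec")
    if config.synthetic_spec is not None:
        em, _ = synthetic.generate(config.synthetic_spec)
    else:
        em = read_expression(config.input_path, config.input_format)
    if config.annotations_path:
        em.annotations = read_annotations(config.annotations_path)
    return em


@_stage("filter")
def _filter(config: PipelineConfig, em: ExpressionMatrix) -> ExpressionMatrix:
    return filter_genes(
        em,
        max_zero_fraction=config.max_zero_fraction,
        mean_lowest_pct=config.mean_lowest_pct,
        var_lowest_pct=config.var_lowest_pct,
    )


@_stage("mine")
def _mine(config: PipelineConfig, em: ExpressionMatrix):
    corr = coexpression.spearman_matrix(em)
    net = coexpression.to_network(corr, em.gene_ids, normalize=config.normalize_weights)
    return coexpression.mine_modules(
        net,
        gamma=config.gamma,
        lambda_=config.lambda_,
        t=config.t,
        beta=config.beta,
        min_size=config.min_module_size,
    )


@_stage("eigengenes")
def _eigengenes(em: ExpressionMatrix, modules):
    return eigengene.eigengenes_for_modules(em, modules)


@_stage("select")
def _select(config: PipelineConfig, es):
    return filtering.select_informative(es, config.kurtosis_threshold)


@_stage("index")
def _index(config: PipelineConfig, es):
    return spatial.pairwise_clustering_indices(
        es, n_sim=config.n_sims, seed=config.seed
    )


@_stage("splom")
def _splom(config: PipelineConfig, es, cim, out: Path):
    viz.render_splom(es, cim, out, bins=config.bins)


def _write_manifest(config: PipelineConfig, res: PipelineResult) -> None:
    manifest = {
        "parameters": config.to_dict(),
        "artifacts": {k: str(v) for k, v in res.artifacts.items()},
        "n_modules": len(res.modules),
        "n_selected": int(res.eigengenes.selected.sum()) if res.eigengenes else 0,
    }
    with open(res.run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
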