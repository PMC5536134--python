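import numpy as np
import pytest

import fvfc

# Analysis settings used for the synthetic study conditions throughout the
# suite: gamma sits midway between the post-dropout within-module rank
# correlation (~0.5) and the background maximum (~0.17); module floor and
# kurtosis threshold follow the workflow's usual choices.
BENCH_GAMMA = 0.48
BENCH_MIN_SIZE = 5
BENCH_KURT_THRESHOLD = 5.0


@pytest.fixture(scope="session")
def bench():
    """Full pipeline products on the default synthetic study conditions
    (seed 1), shared across tests for speed."""
    spec = fvfc.default_spec(1)
    em, truth = fvfc.generate(spec)
    filtered = fvfc.filter_genes(em)
    corr = fvfc.spearman_matrix(filtered)
    net = fvfc.to_network(corr, filtered.gene_ids)
    modules = fvfc.mine_modules(net, gamma=BENCH_GAMMA, min_size=BENCH_MIN_SIZE)
    es = fvfc.eigengenes_for_modules(filtered, modules)
    es = fvfc.select_informative(es, BENCH_KURT_THRESHOLD)
    return {
        "spec": spec,
        "em": em,
        "truth": truth,
        "filtered": filtered,
        "corr": corr,
        "net": net,
        "modules": modules,
        "eigengenes": es,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_em(rng):
    """10 genes x 30 cells of positive noise, no zeros."""
    values = 5.0 + rng.standard_normal((10, 30))
    return fvfc.ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(10)],
        cell_ids=[f"c{j}" for j in range(30)],
    )
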