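import numpy as np
import pytest
from scipy.stats import rankdata

import fvfc
from fvfc.coexpression import adaptive_density_threshold, module_density
from fvfc.errors import ConstantGeneError


def _em(values):
    values = np.asarray(values, dtype=float)
    return fvfc.ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"c{j}" for j in range(values.shape[1])],
    )


class TestSpearman:
    def test_monotone_pairs(self):
        em = _em([[1, 2, 3], [2, 4, 9], [9, 4, 2]])
        corr = fvfc.spearman_matrix(em)
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_matches_rank_pearson_oracle(self, rng):
        # oracle: explicit average-rank transform + explicit Pearson formula
        values = rng.standard_normal((10, 30))
        values[0, :5] = values[0, 5]  # introduce ties
        corr = fvfc.spearman_matrix(_em(values))
        ranks = np.vstack([rankdata(row) for row in values])
        for i in range(10):
            for j in range(10):
                x, y = ranks[i] - ranks[i].mean(), ranks[j] - ranks[j].mean()
                rho = np.sum(x * y) / np.sqrt(np.sum(x * x) * np.sum(y * y))
                assert corr[i, j] == pytest.approx(rho, abs=1e-12)

    def test_constant_gene_rejected(self):
        em = _em([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ConstantGeneError, match="g0"):
            fvfc.spearman_matrix(em)

    def test_too_few_cells(self):
        with pytest.raises(fvfc.errors.FvfcError):
            fvfc.spearman_matrix(_em([[1, 2], [2, 1]]))


class TestToNetwork:
    def test_absolute_value(self):
        corr = np.array([[1.0, -0.8], [-0.8, 1.0]])
        net = fvfc.to_network(corr, ["a", "b"])
        assert net.weights[0, 1] == pytest.approx(0.8)
        assert net.weights[0, 0] == 0.0

    def test_uniform_weights_stay_equal_under_normalization(self):
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        net = fvfc.to_network(corr, list("abc"), normalize=True)
        off = net.weights[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_normalization_matches_row_sum_oracle(self, rng):
        corr = rng.uniform(-1, 1, size=(8, 8))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        net = fvfc.to_network(corr, [f"g{i}" for i in range(8)], normalize=True)
        w = np.abs(corr)
        np.fill_diagonal(w, 0.0)
        d = w.sum(axis=1)
        expected = w / np.sqrt(np.outer(d, d))
        expected /= expected.max()
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(net.weights, expected, atol=1e-12)


def _uniform_net(w):
    w = np.asarray(w, dtype=float)
    np.fill_diagonal(w, 0.0)
    return fvfc.CorrelationNetwork(w, [f"g{i}" for i in range(w.shape[0])])


class TestMineModules:
    def test_single_planted_clique(self):
        # genes 0-4 pairwise 0.9, everything else 0.1: traced by hand, the
        # greedy growth admits no background vertex (average weight 0.1
        # is far below the adaptive threshold), leaving exactly the clique
        w = np.full((10, 10), 0.1)
        w[:5, :5] = 0.9
        mods = fvfc.mine_modules(_uniform_net(w), gamma=0.5, min_size=5)
        assert [sorted(m.members) for m in mods] == [[0, 1, 2, 3, 4]]

    def test_gamma_above_max_weight_yields_empty(self):
        w = np.full((6, 6), 0.9)
        mods = fvfc.mine_modules(_uniform_net(w), gamma=0.95, min_size=2)
        assert mods == []

    def test_two_planted_cliques(self):
        w = np.full((20, 20), 0.05)
        w[:6, :6] = 0.9
        w[6:12, 6:12] = 0.9
        mods = fvfc.mine_modules(_uniform_net(w), gamma=0.5, min_size=5)
        assert [sorted(m.members) for m in mods] == [
            [0, 1, 2, 3, 4, 5],
            [6, 7, 8, 9, 10, 11],
        ]

    def test_density_invariant_and_sorting(self, rng):
        w = rng.uniform(0, 0.3, size=(30, 30))
        w = (w + w.T) / 2
        w[:8, :8] = rng.uniform(0.8, 1.0)
        w[20:26, 20:26] = rng.uniform(0.7, 0.9)
        w = (w + w.T) / 2
        net = _uniform_net(w)
        mods = fvfc.mine_modules(net, gamma=0.6, min_size=4)
        assert mods, "expected at least one module"
        sizes = [m.size for m in mods]
        assert sizes == sorted(sizes, reverse=True)
        for m in mods:
            dens = module_density(net.weights, m.members)
            assert dens >= adaptive_density_threshold(0.6, m.size, 1.0, 1.0) - 1e-12

    def test_deterministic(self, rng):
        w = rng.uniform(0, 1, size=(25, 25))
        w = (w + w.T) / 2
        net = _uniform_net(w)
        a = fvfc.mine_modules(net, gamma=0.7, min_size=3)
        b = fvfc.mine_modules(net, gamma=0.7, min_size=3)
        assert [m.members for m in a] == [m.members for m in b]

    def test_overlap_merging(self):
        # two heavy cliques sharing 3 of 6 vertices merge at beta=0.4
        w = np.full((12, 12), 0.05)
        for block in ([0, 1, 2, 3, 4, 5], [3, 4, 5, 6, 7, 8]):
            for a in block:
                for b in block:
                    if a != b:
                        w[a, b] = 0.9
        mods = fvfc.mine_modules(_uniform_net(w), gamma=0.5, min_size=4, beta=0.4)
        assert len(mods) == 1
        assert sorted(mods[0].members) == list(range(9))

    def test_planted_block_recovery_jaccard(self, rng):
        # w_in = 0.9, w_out = 0.05, three blocks of 20 in 80 genes
        m = 80
        w = 0.05 + 0.02 * rng.random((m, m))
        w = (w + w.T) / 2
        blocks = [list(range(0, 20)), list(range(20, 40)), list(range(40, 60))]
        for blk in blocks:
            sub = 0.9 + 0.05 * rng.random((20, 20))
            sub = (sub + sub.T) / 2
            w[np.ix_(blk, blk)] = np.clip(sub, 0, 1)
        mods = fvfc.mine_modules(_uniform_net(w), gamma=0.5, min_size=5)
        for blk in blocks:
            jac = max(
                len(set(blk) & set(mo.members)) / len(set(blk) | set(mo.members))
                for mo in mods
            )
            assert jac >= 0.9
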