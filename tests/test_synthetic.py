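import json

import numpy as np
import pytest

import fvfc
from fvfc.errors import FvfcError
from fvfc.synthetic import write_dataset


class TestSpecValidation:
    def test_infeasible_correlation(self):
        with pytest.raises(FvfcError):
            fvfc.ModuleSpec(size=5, within_corr=1.0)
        with pytest.raises(FvfcError):
            fvfc.ModuleSpec(size=5, within_corr=0.0)

    def test_bad_rates(self):
        with pytest.raises(FvfcError):
            fvfc.SyntheticSpec(n_cells=10, n_background_genes=5, modules=[],
                               dropout_rate=1.0)


class TestGenerate:
    def test_reproducible_bitwise(self):
        spec = fvfc.default_spec(3)
        a, _ = fvfc.generate(spec)
        b, _ = fvfc.generate(spec)
        assert np.array_equal(a.values, b.values)
        assert a.gene_ids == b.gene_ids

    def test_two_group_latent_factor_is_bimodal(self):
        spec = fvfc.SyntheticSpec(
            n_cells=400, n_background_genes=0,
            modules=[fvfc.ModuleSpec(size=5, n_cell_groups=2, group_shift=5.0)],
            dropout_rate=0.0, seed=4,
        )
        _, truth = fvfc.generate(spec)
        factor = np.asarray(truth["factors"]["M1"])
        # oracle: kurtosis of the latent factor directly
        assert fvfc.kurtosis(factor) < 3.0

    def test_sharp_factor_has_high_kurtosis(self):
        spec = fvfc.SyntheticSpec(
            n_cells=400, n_background_genes=0,
            modules=[fvfc.ModuleSpec(size=5, factor_dist="sharp")],
            dropout_rate=0.0, seed=4,
        )
        _, truth = fvfc.generate(spec)
        assert fvfc.kurtosis(np.asarray(truth["factors"]["M1"])) > 6.0

    def test_within_corr_hits_spearman_target(self):
        spec = fvfc.SyntheticSpec(
            n_cells=600, n_background_genes=0,
            modules=[fvfc.ModuleSpec(size=10, within_corr=0.7),
                     fvfc.ModuleSpec(size=10, within_corr=0.7,
                                     factor_dist="sharp")],
            dropout_rate=0.0, seed=5,
        )
        em, truth = fvfc.generate(spec)
        corr = fvfc.spearman_matrix(em)
        for name in ("M1", "M2"):
            idx = [em.gene_ids.index(g) for g in truth["modules"][name]]
            off = corr[np.ix_(idx, idx)][~np.eye(len(idx), dtype=bool)]
            assert off.mean() == pytest.approx(0.7, abs=0.05)

    def test_heavy_dropout_genes_removed_by_default_filters(self):
        spec = fvfc.SyntheticSpec(
            n_cells=100, n_background_genes=50, modules=[],
            dropout_rate=0.9, seed=6,
        )
        em, _ = fvfc.generate(spec)
        zero_frac = (em.values == 0).mean(axis=1)
        assert (zero_frac > 0.5).all()  # oracle: direct zero-count check
        with pytest.raises(FvfcError):
            fvfc.filter_genes(em)  # everything violates the zero rule

    def test_dropout_rate_roughly_respected(self):
        em, _ = fvfc.generate(fvfc.default_spec(2))
        frac = (em.values == 0).mean()
        assert frac == pytest.approx(0.1, abs=0.01)


class TestGroundTruthSidecar:
    def test_write_dataset_round_trip(self, tmp_path):
        spec = fvfc.SyntheticSpec(
            n_cells=50, n_background_genes=10,
            modules=[fvfc.ModuleSpec(size=4, n_cell_groups=2, group_shift=3.0)],
            dropout_rate=0.0, seed=8,
        )
        paths = write_dataset(spec, tmp_path, annotate_module="M1")
        em = fvfc.read_expression(paths["expression"], "dense-tsv")
        assert em.n_genes == 14 and em.n_cells == 50
        truth = json.loads(paths["truth"].read_text())
        assert truth["modules"]["M1"] == [f"M1_G{j}" for j in range(1, 5)]
        labels = fvfc.read_annotations(paths["annotations"])
        assert set(labels.values()) <= {"group0", "group1"}
        assert len(labels) == 50


class TestCoincidentGroups:
    def test_shared_key_shares_partition(self):
        spec = fvfc.SyntheticSpec(
            n_cells=200, n_background_genes=0,
            modules=[
                fvfc.ModuleSpec(size=4, n_cell_groups=2, group_shift=3.0,
                                group_key="k"),
                fvfc.ModuleSpec(size=4, n_cell_groups=2, group_shift=3.0,
                                group_key="k"),
                fvfc.ModuleSpec(size=4, n_cell_groups=2, group_shift=3.0),
            ],
            dropout_rate=0.0, seed=9,
        )
        _, truth = fvfc.generate(spec)
        g = truth["cell_groups"]
        assert g["M1"] == g["M2"]
        assert g["M1"] != g["M3"]

    def test_coincident_pair_clusters_harder_than_independent(self):
        """Modules on the same cell partition make a two-clump scatter with a
        far more negative clustering index than independent partitions."""
        spec = fvfc.SyntheticSpec(
            n_cells=500, n_background_genes=0,
            modules=[
                fvfc.ModuleSpec(size=20, n_cell_groups=2, group_shift=4.0,
                                group_key="shared"),
                fvfc.ModuleSpec(size=20, n_cell_groups=2, group_shift=4.0,
                                group_key="shared"),
                fvfc.ModuleSpec(size=20, n_cell_groups=2, group_shift=4.0),
            ],
            dropout_rate=0.0, seed=7,
        )
        em, truth = fvfc.generate(spec)
        mods = [
            fvfc.GeneModule(k + 1, [em.gene_ids.index(g)
                                    for g in truth["modules"][f"M{k + 1}"]])
            for k in range(3)
        ]
        es = fvfc.eigengenes_for_modules(em, mods)
        z_co = fvfc.clustering_index(
            np.column_stack([es.vectors[0], es.vectors[1]]), seed=1
        )
        z_ind = fvfc.clustering_index(
            np.column_stack([es.vectors[0], es.vectors[2]]), seed=1
        )
        assert z_co < -3
        assert z_co < z_ind  # ordering, not a fixed value
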