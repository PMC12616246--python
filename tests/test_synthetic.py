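import numpy as np
import pandas as pd
import pytest

from phenoscape.preprocessing import arcsinh_transform
from phenoscape.shift import signed_emd
from phenoscape.synthetic import (
    ConfigurationError,
    CytometrySimConfig,
    ScrnaSimConfig,
    generate_cytometry_experiment,
    generate_scrna_counts,
)


class TestCytometryGenerator:
    def test_identical_seed_bit_identical(self):
        config = CytometrySimConfig(conditions=["a", "b"], cells_per_condition=200, seed=5,
                                    doublet_rate=0.1)
        t1, g1 = generate_cytometry_experiment(config)
        t2, g2 = generate_cytometry_experiment(config)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        assert g1.cell_code == g2.cell_code

    def test_raw_values_non_negative(self):
        table, _ = generate_cytometry_experiment(
            CytometrySimConfig(conditions=["a"], cells_per_condition=300, seed=1)
        )
        assert (table.values >= 0).all()

    def test_null_config_gives_near_zero_emd(self):
        config = CytometrySimConfig(conditions=["a", "b"], cells_per_condition=4000, seed=2)
        table, _ = generate_cytometry_experiment(config)
        t = arcsinh_transform(table)
        emd = signed_emd(t.where_condition("a")["pSTAT3"], t.where_condition("b")["pSTAT3"])
        assert abs(emd) < 0.05

    def test_planted_shift_recovered_and_improves_with_n(self):
        errs = {}
        for n in (500, 5000):
            config = CytometrySimConfig(
                conditions=["ctrl", "shift"],
                cells_per_condition=n,
                shift_map={("shift", "pAKT"): 1.0},
                seed=3,
            )
            table, _ = generate_cytometry_experiment(config)
            t = arcsinh_transform(table)
            emd = signed_emd(
                t.where_condition("shift")["pAKT"], t.where_condition("ctrl")["pAKT"]
            )
            errs[n] = abs(emd - 1.0)
        assert errs[5000] < 0.1
        assert errs[5000] <= errs[500]

    def test_realized_apoptosis_fraction_within_three_se(self):
        n, p = 3000, 0.3
        config = CytometrySimConfig(
            conditions=["c"], cells_per_condition=n, apoptosis_fraction={"c": p}, seed=4
        )
        _, truth = generate_cytometry_experiment(config)
        realized = np.mean(np.array(truth.cell_state) == "apoptotic")
        assert abs(realized - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_singlet_top_k_channels_match_true_code(self):
        config = CytometrySimConfig(
            conditions=[f"c{i}" for i in range(12)], cells_per_condition=150,
            doublet_rate=0.0, seed=6,
        )
        table, truth = generate_cytometry_experiment(config)
        bc = table.data[[f"BC{i+1}" for i in range(9)]].to_numpy()
        top4 = np.sort(np.argsort(-bc, axis=1)[:, :4], axis=1)
        for row, code in zip(top4, truth.cell_code):
            assert tuple(row) == code

    def test_doublets_are_channel_sums(self):
        config = CytometrySimConfig(conditions=["a"], cells_per_condition=100,
                                    doublet_rate=0.2, seed=7)
        table, truth = generate_cytometry_experiment(config)
        assert truth.is_doublet.sum() == 20
        # doublet DNA content roughly doubles the singlet level
        dna = table["DNA1"]
        assert dna[truth.is_doublet].mean() > 1.7 * dna[~truth.is_doublet].mean()

    def test_dependency_strength_shapes_conditional_variance(self):
        config = CytometrySimConfig(
            conditions=["weak", "strong"],
            cells_per_condition=3000,
            dependency_map={
                ("weak", ("pERK", "pS6")): 0.1,
                ("strong", ("pERK", "pS6")): 0.9,
            },
            seed=8,
        )
        table, _ = generate_cytometry_experiment(config)
        t = arcsinh_transform(table)

        def resid_sd(cond):
            sub = t.where_condition(cond)
            x, y = sub["pERK"], sub["pS6"]
            order = np.argsort(x)
            halves = np.array_split(y[order], 20)
            return np.mean([h.std() for h in halves])

        assert resid_sd("strong") < resid_sd("weak")

    def test_panel_without_dna_or_viability_rejected(self):
        panel = [("pSTAT3", "PTM")] + [(f"BC{i}", "barcode") for i in range(9)]
        with pytest.raises(ConfigurationError):
            CytometrySimConfig(conditions=["a"], marker_panel=panel)

    def test_invalid_maps_rejected(self):
        with pytest.raises(ConfigurationError):
            CytometrySimConfig(conditions=["a"], shift_map={("zzz", "pSTAT3"): 1.0})
        with pytest.raises(ConfigurationError):
            CytometrySimConfig(conditions=["a"], apoptosis_fraction={"a": 1.5})
        with pytest.raises(ConfigurationError):
            CytometrySimConfig(conditions=["a"], cells_per_condition=0)


class TestScrnaGenerator:
    def test_counts_are_non_negative_integers(self, scrna_experiment):
        adata, _ = scrna_experiment
        X = np.asarray(adata.X.todense())
        assert (X >= 0).all()
        assert np.array_equal(X, np.round(X))

    def test_metadata_recomputable_from_matrix(self, scrna_experiment):
        adata, _ = scrna_experiment
        X = np.asarray(adata.X.todense())
        np.testing.assert_array_equal(adata.obs["total_umis"], X.sum(axis=1))
        np.testing.assert_array_equal(adata.obs["n_genes"], (X > 0).sum(axis=1))
        mito_cols = [g.startswith("MT-") for g in adata.var_names]
        np.testing.assert_allclose(
            adata.obs["mito_fraction"],
            X[:, mito_cols].sum(axis=1) / np.maximum(X.sum(axis=1), 1),
        )

    def test_pure_revival_cells_favor_rev_genes(self):
        config = ScrnaSimConfig(n_cells=200, program_mix=np.ones(200), seed=9)
        adata, _ = generate_scrna_counts(config)
        X = np.asarray(adata.X.todense())
        rev = [g.startswith("REVCSC") for g in adata.var_names]
        pro = [g.startswith("PROCSC") for g in adata.var_names]
        assert X[:, rev].mean() > X[:, pro].mean()

    def test_zero_cells_gives_empty_valid_matrix(self):
        adata, truth = generate_scrna_counts(ScrnaSimConfig(n_cells=0, seed=0))
        assert adata.n_obs == 0
        assert adata.n_vars == 400
        assert truth.program_mix.size == 0

    def test_determinism(self):
        c = ScrnaSimConfig(n_cells=100, seed=11)
        a1, t1 = generate_scrna_counts(c)
        a2, t2 = generate_scrna_counts(c)
        np.testing.assert_array_equal(
            np.asarray(a1.X.todense()), np.asarray(a2.X.todense())
        )
        np.testing.assert_array_equal(t1.program_mix, t2.program_mix)

    def test_overlapping_programs_rejected(self):
        with pytest.raises(ConfigurationError, match="disjoint"):
            ScrnaSimConfig(pro_gene_names=["A", "B"], rev_gene_names=["B", "C"])
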