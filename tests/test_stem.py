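import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy.stats import spearmanr

from phenoscape.stem import (
    GeneProgramScorer,
    QCThresholds,
    compute_stem_scores,
    log_normalize,
    log_transform,
    normalize_counts,
    qc_filter,
    read_counts,
    stem_cell_index,
    stem_index_summary,
)


def _adata(umi, genes, mito, ratio):
    n = len(umi)
    obs = pd.DataFrame(
        {
            "total_umis": umi,
            "n_genes": genes,
            "mito_fraction": mito,
            "umi_read_ratio": ratio,
        },
        index=[f"c{i}" for i in range(n)],
    )
    X = sparse.csr_matrix(np.ones((n, 3)))
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=["g1", "g2", "g3"]))


class TestQCFilter:
    def test_toy_survivors(self):
        """Apply the quoted exclusion bounds rule by rule: one cell survives."""
        adata = _adata(
            umi=[5_000, 500, 5_000, 40_000],
            genes=[2_000, 400, 2_000, 8_000],
            mito=[0.05, 0.05, 0.25, 0.05],
            ratio=[0.2, 0.2, 0.2, 0.2],
        )
        kept, report = qc_filter(adata, QCThresholds(min_cells_per_gene=0))
        assert kept.n_obs == 1
        assert list(kept.obs_names) == ["c0"]
        assert report.removed == {"umi": 2, "genes": 0, "mito": 1, "umi_read_ratio": 0}

    def test_boundary_values_are_kept(self):
        """Exclusion bounds are strict inequalities: exactly-at-bound cells stay."""
        adata = _adata(
            umi=[1_000, 32_500, 999],
            genes=[300, 7_000, 500],
            mito=[0.20, 0.20, 0.0],
            ratio=[0.4, 0.4, 0.2],
        )
        kept, _ = qc_filter(adata, QCThresholds(min_cells_per_gene=0))
        assert list(kept.obs_names) == ["c0", "c1"]

    def test_conservation_and_empty_input(self):
        rng = np.random.default_rng(0)
        adata = _adata(
            umi=rng.integers(100, 50_000, 50),
            genes=rng.integers(100, 9_000, 50),
            mito=rng.uniform(0, 0.4, 50),
            ratio=rng.uniform(0, 0.6, 50),
        )
        kept, report = qc_filter(adata, QCThresholds(min_cells_per_gene=0))
        assert report.n_cells_kept + sum(report.removed.values()) == report.n_cells_in

        empty, report0 = qc_filter(adata[:0].copy(), QCThresholds(min_cells_per_gene=0))
        assert empty.n_obs == 0
        assert sum(report0.removed.values()) == 0

    def test_gene_filter_applied_after_cells(self):
        n = 30
        X = np.zeros((n, 3))
        X[:, 0] = 5  # detected in all 30 cells
        X[:5, 1] = 3  # detected in 5 cells only
        adata = ad.AnnData(
            X=sparse.csr_matrix(X),
            obs=pd.DataFrame(
                {
                    "total_umis": [5_000] * n,
                    "n_genes": [1_000] * n,
                    "mito_fraction": [0.05] * n,
                    "umi_read_ratio": [0.2] * n,
                },
                index=[f"c{i}" for i in range(n)],
            ),
            var=pd.DataFrame(index=["keep", "rare", "absent"]),
        )
        kept, report = qc_filter(adata, QCThresholds(min_cells_per_gene=25))
        assert list(kept.var_names) == ["keep"]
        assert report.n_genes_kept == 1


class TestNormalization:
    def test_quoted_rule_arithmetic_self_consistent_example(self):
        """[10, 190]: gene1 = 5% exactly (kept, strict >), gene2 = 95% (excluded)."""
        norm, kept = normalize_counts(np.array([[10.0, 190.0]]))
        assert kept.all()
        np.testing.assert_allclose(norm, [[10_000.0, 190_000.0]])

    def test_all_genes_highly_expressed_degenerates(self):
        """[10, 90]: both genes exceed 5% of the cell total, so the size-factor
        base is empty and the cell is flagged for dropping (errors clause)."""
        with pytest.warns(UserWarning, match="flagged"):
            norm, kept = normalize_counts(np.array([[10.0, 90.0]]))
        assert not kept[0]
        assert np.isnan(norm[0]).all()

    def test_uniform_cell_sums_to_scale(self):
        X = np.full((1, 30), 7.0)  # each gene 1/30 of the total, none > 5%
        norm, kept = normalize_counts(X)
        assert kept.all()
        assert norm.sum() == pytest.approx(10_000.0)

    def test_integer_rescaling_invariance(self):
        """The >5% rule is scale-free: c * counts has identical lognorm profile."""
        rng = np.random.default_rng(1)
        X = rng.poisson(3.0, (5, 40)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        n1, k1 = normalize_counts(X)
        n2, k2 = normalize_counts(7 * X)
        np.testing.assert_array_equal(k1, k2)
        np.testing.assert_allclose(log_transform(n1[k1]), log_transform(n2[k2]), rtol=1e-12)

    def test_log_transform_zero(self):
        assert log_transform(np.array([0.0]))[0] == 0.0


class TestGeneProgramScorer:
    def test_identical_program_and_background_scores_zero(self):
        X = pd.DataFrame(np.ones((10, 60)), columns=[f"g{i}" for i in range(60)])
        scores = GeneProgramScorer(["g0"], random_state=0).fit_transform(X)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_constructed_mean_difference(self):
        """One program gene at 2 in a cell whose matched controls sit at 1."""
        n_cells, n_ctrl = 20, 30
        cols = {f"ctrl{i}": np.ones(n_cells) for i in range(n_ctrl)}
        prog = np.ones(n_cells)
        prog[0], prog[1] = 2.0, 0.0  # mean stays 1 -> same bin as controls
        cols["prog"] = prog
        X = pd.DataFrame(cols)
        scores = GeneProgramScorer(["prog"], random_state=0).fit_transform(X)
        assert scores[0] == pytest.approx(1.0)
        assert scores[2] == pytest.approx(0.0)

    def test_seeded_sampling_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.uniform(0, 2, (50, 200)),
                         columns=[f"g{i}" for i in range(200)])
        s1 = GeneProgramScorer(["g0", "g1"], random_state=7).fit_transform(X)
        s2 = GeneProgramScorer(["g0", "g1"], random_state=7).fit_transform(X)
        np.testing.assert_array_equal(s1, s2)

    def test_missing_genes_dropped_empty_program_rejected(self):
        X = pd.DataFrame(np.ones((5, 10)), columns=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="empty"):
            GeneProgramScorer(["nope"]).fit(X)
        scorer = GeneProgramScorer(["g0", "nope"]).fit(X)
        assert scorer.used_program_genes_ == ["g0"]


class TestStemIndex:
    def test_subtraction_identity(self):
        assert stem_cell_index([0.2], [0.5])[0] == pytest.approx(0.3)
        assert stem_cell_index([0.4], [0.4])[0] == 0.0
        with pytest.raises(ValueError):
            stem_cell_index([0.1, 0.2], [0.1])

    def test_summary_quartiles(self):
        idx = np.arange(101, dtype=float)
        summary = stem_index_summary(idx)
        row = summary.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (25.0, 50.0, 75.0)

    def test_planted_program_mix_rank_correlates(self, scrna_experiment):
        adata, truth = scrna_experiment
        kept, _ = qc_filter(adata)
        lognorm = log_normalize(kept)
        scores = compute_stem_scores(
            lognorm, adata.uns["programs"]["proCSC"], adata.uns["programs"]["revCSC"]
        )
        kept_idx = [i for i, name in enumerate(adata.obs_names)
                    if name in set(lognorm.obs_names)]
        rho = spearmanr(truth.program_mix[kept_idx], scores.stem_index).statistic
        assert rho > 0.8

    def test_extreme_mix_cells_ordered(self, scrna_experiment):
        adata, truth = scrna_experiment
        kept, _ = qc_filter(adata)
        lognorm = log_normalize(kept)
        scores = compute_stem_scores(
            lognorm, adata.uns["programs"]["proCSC"], adata.uns["programs"]["revCSC"]
        )
        kept_idx = np.array(
            [i for i, name in enumerate(adata.obs_names) if name in set(lognorm.obs_names)]
        )
        w = truth.program_mix[kept_idx]
        assert np.median(scores.stem_index[w > 0.9]) > np.median(scores.stem_index[w < 0.1])

    def test_scanpy_cross_check(self, scrna_experiment):
        """Independent oracle: scanpy's gene scoring agrees in rank order."""
        sc = pytest.importorskip("scanpy")
        adata, _ = scrna_experiment
        kept, _ = qc_filter(adata)
        lognorm = log_normalize(kept)
        rev = adata.uns["programs"]["revCSC"]
        ours = compute_stem_scores(lognorm, adata.uns["programs"]["proCSC"], rev)
        ref = lognorm.copy()
        sc.tl.score_genes(ref, rev, score_name="ref_rev", ctrl_size=50, n_bins=25)
        rho = spearmanr(ours.rev_score, ref.obs["ref_rev"]).statistic
        assert rho > 0.9


def test_mtx_round_trip(tmp_path, scrna_experiment):
    from phenoscape.synthetic import write_scrna_experiment

    adata, truth = scrna_experiment
    write_scrna_experiment(adata, truth, tmp_path)
    back = read_counts(
        tmp_path / "matrix.mtx",
        tmp_path / "genes.tsv",
        tmp_path / "barcodes.tsv",
        tmp_path / "metadata.tsv",
    )
    assert back.shape == adata.shape
    assert list(back.var_names) == list(adata.var_names)
    np.testing.assert_array_equal(
        np.asarray(back.X.todense()), np.asarray(adata.X.todense())
    )
    assert "umi_read_ratio" in back.obs.columns
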