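import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from equiqtl import SimConfig, simulate_expression, simulate_genotypes
from equiqtl.io_formats import CountMatrix
from equiqtl.exprprep import (
    _ks_d,
    apply_gene_filter,
    ks_cutoff_cohort,
    ks_cutoff_pair,
    normalized_counts,
    residualize,
    size_factors,
    vst,
)


def _cm(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(gene_ids=genes, sample_ids=samples, counts=counts)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        cm = _cm([[10, 10], [5, 5], [100, 100]])
        np.testing.assert_allclose(size_factors(cm), [1.0, 1.0])

    def test_doubled_sample_splits_geometrically(self):
        cm = _cm([[10, 20], [6, 12], [100, 200]])
        np.testing.assert_allclose(
            size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 500, size=(5, 3))
        cm = _cm(counts)
        ref = np.exp(np.mean(np.log(counts), axis=1))
        oracle = [np.median(counts[:, j] / ref) for j in range(3)]
        np.testing.assert_allclose(size_factors(cm), oracle, atol=1e-12)

    def test_no_common_gene_errors(self):
        cm = _cm([[10, 0], [0, 10]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(cm)


class TestVst:
    def test_zero_count_maps_to_zero(self):
        cm = _cm([[0, 3]])
        em = vst(cm, np.array([1.0, 1.0]))
        assert em.values[0, 0] == 0.0

    def test_monotone_in_counts(self):
        cm = _cm([[3, 7]])
        em = vst(cm, np.array([1.0, 1.0]))
        assert em.values[0, 0] < em.values[0, 1]

    def test_flattens_sd_vs_mean_slope(self):
        rng = np.random.default_rng(1)
        means = np.exp(rng.uniform(np.log(5), np.log(2000), size=300))
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + means[:, None]),
                                       size=(300, 50))
        cm = _cm(counts)
        em = vst(cm, np.ones(50))

        def slope(mat):
            mu, sd = mat.mean(axis=1), mat.std(axis=1)
            return np.polyfit(mu, sd, 1)[0]

        assert abs(slope(counts)) >= 5 * abs(slope(em.values))


class TestKsD:
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=40),
        st.lists(st.floats(-50, 50), min_size=2, max_size=40),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_scipy_statistic(self, a, b):
        a, b = np.array(a), np.array(b)
        assert _ks_d(a, b) == pytest.approx(
            stats.ks_2samp(a, b).statistic, abs=1e-12
        )


class TestKsCutoffPair:
    def test_identical_profiles_flagged_at_grid_max(self):
        x = np.linspace(1, 300, 500)
        cutoff, resolved = ks_cutoff_pair(x, x)
        assert cutoff == 300 and not resolved

    def test_symmetric_in_samples(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 100, size=400)
        b = rng.uniform(0, 100, size=400)
        assert ks_cutoff_pair(a, b) == ks_cutoff_pair(b, a)

    def test_hand_worked_grid_walk_stops_at_two(self):
        # 10 genes. Four discrepant low genes (pair-mean < 2) dominate the
        # starting D; cutoff 2 removes them, dropping D to 1/6; cutoff 4
        # then removes a concordant mid gene, which *raises* D to 1/5, so
        # the three stopping rules are all met at cutoff 2.
        a = np.array([0.8, 0.8, 0.8, 0.8, 3.0, 10, 20, 30, 40, 50])
        b = np.array([2.0, 2.0, 2.0, 2.0, 3.0, 11, 20, 30, 40, 50])
        pm = (a + b) / 2
        d = [
            stats.ks_2samp(a[pm >= c], b[pm >= c]).statistic for c in (0, 2, 4)
        ]
        assert d[0] >= 0.4
        assert d[1] == pytest.approx(1 / 6)
        assert d[2] == pytest.approx(1 / 5)
        assert d[1] < d[0] - 1e-4 and d[1] < d[2]
        cutoff, resolved = ks_cutoff_pair(a, b)
        assert (cutoff, resolved) == (2, True)

    def test_too_few_genes_flags(self):
        a = np.array([1.0, 2.0])
        b = np.array([1.5, 2.5])
        cutoff, resolved = ks_cutoff_pair(a, b)
        assert not resolved


class TestKsCutoffCohort:
    def test_identical_samples_flag_all_pairs_and_keep_all_genes(self):
        col = np.concatenate([np.zeros(3), np.arange(1, 40, dtype=float)])
        counts = np.tile(col[:, None], (1, 3)).astype(int)
        res = ks_cutoff_cohort(_cm(counts))
        assert len(res.unresolved_pairs) == 3
        assert res.mean_cutoff == 0.0
        # prefiltered genes (>= 1 read somewhere) all retained
        assert len(res.genes_retained) == 39

    def test_pair_count_is_n_choose_2(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 200, size=(50, 9))
        res = ks_cutoff_cohort(_cm(counts))
        assert len(res.pairwise_cutoffs) == 9 * 8 // 2

    def test_noise_gene_recall_and_expressed_retention(self):
        cfg = SimConfig(seed=21, n_unrelated=20, n_fam1=0, n_fam2=0,
                        n_chroms=1, n_snps=10, n_genes=500, n_noise_genes=300,
                        noise_mean_max=20.0)
        g = simulate_genotypes(cfg)
        counts, truth = simulate_expression(g, cfg)
        res = ks_cutoff_cohort(counts)
        retained = set(res.genes_retained)
        noise = set(truth.noise_genes)
        expressed = set(counts.gene_ids) - noise
        noise_removed = len(noise - retained) / len(noise)
        expr_kept = len(expressed & retained) / len(expressed)
        assert noise_removed >= 0.9
        assert expr_kept >= 0.95


class TestResidualize:
    def _expr(self, values, samples=None):
        values = np.asarray(values, dtype=float)
        samples = samples or [f"s{j}" for j in range(values.shape[1])]
        from equiqtl.exprprep import ExpressionMatrix

        return ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(values.shape[0])],
            sample_ids=samples,
            values=values,
            size_factors=np.ones(values.shape[1]),
        )

    def test_intercept_only_is_mean_centering(self):
        rng = np.random.default_rng(0)
        em = self._expr(rng.normal(size=(5, 12)))
        rm = residualize(em, covariates=None, k_factors=0)
        np.testing.assert_allclose(
            rm.residuals, em.values - em.values.mean(axis=1, keepdims=True),
            atol=1e-12,
        )

    def test_residual_means_are_zero(self):
        rng = np.random.default_rng(1)
        em = self._expr(rng.normal(size=(20, 30)))
        rm = residualize(em, covariates=None, k_factors=3)
        assert np.abs(rm.residuals.mean(axis=1)).max() < 1e-8

    def test_planted_batch_factor_removed(self):
        cfg = SimConfig(seed=31, n_chroms=1, n_snps=20, n_genes=200,
                        n_noise_genes=0, n_batch_factors=1)
        g = simulate_genotypes(cfg)
        counts, truth = simulate_expression(g, cfg)
        em = vst(counts, size_factors(counts))
        rm = residualize(em, covariates=None, k_factors=1)
        batch = truth.batch_scores[0]
        cors = [
            abs(np.corrcoef(rm.residuals[i], batch)[0, 1])
            for i in range(len(rm.gene_ids))
        ]
        assert np.median(cors) < 0.05

    def test_idempotent_with_reused_factor_basis(self):
        rng = np.random.default_rng(2)
        em = self._expr(rng.normal(size=(30, 25)))
        rm = residualize(em, covariates=None, k_factors=4)
        again = residualize(
            self._expr(rm.residuals), covariates=None, factors=rm.factors
        )
        assert np.abs(again.residuals - rm.residuals).max() < 1e-8

    def test_rank_deficient_covariates_error(self):
        rng = np.random.default_rng(3)
        cov = pd.DataFrame(
            {
                "sample_id": [f"s{j}" for j in range(12)],
                "sex": [0, 1] * 6,
                "age": 10.0,
                "fam1": [1, 0] * 6,
                "fam2": [0, 1] * 6,  # fam1 + fam2 = 1 collides with intercept
                "status": [0, 1] * 6,
            }
        )
        em = self._expr(rng.normal(size=(4, 12)))
        with pytest.raises(ValueError, match="collinear"):
            residualize(em, cov, k_factors=0)

    def test_k_too_large_errors(self):
        rng = np.random.default_rng(4)
        em = self._expr(rng.normal(size=(4, 6)))
        with pytest.raises(ValueError, match="too large"):
            residualize(em, covariates=None, k_factors=5)


def test_apply_gene_filter_subsets_rows():
    cm = _cm(np.arange(12).reshape(4, 3))
    sub = apply_gene_filter(cm, ["g1", "g3"])
    assert sub.gene_ids == ["g1", "g3"]
    np.testing.assert_array_equal(sub.counts, cm.counts[[1, 3]])
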