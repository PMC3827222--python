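import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blocktest.genotypes import GenotypeBlock, code_genotypes
from blocktest.mvnnull import (
    NullModel,
    draw_null_statistics,
    max_chisq_stat,
    mc_pvalue,
    null_correlation,
    simulation_block_p,
    ss_threshold_stat,
)
from blocktest.simulate import draw_genotype_matrix
from blocktest.univariate import adr_statistics


class TestNullCorrelation:
    def test_unit_diagonal(self, null_cohort):
        _, coded, _ = null_cohort
        for adr in (False, True):
            np.testing.assert_allclose(
                np.diag(null_correlation(coded, adr)), 1.0
            )

    def test_additive_dominant_correlation_at_raf_half(self, rng):
        # population value 0.25 / sqrt(0.5 * 0.1875) = 0.8165 under HWE
        g = draw_genotype_matrix(100_000, np.array([0.5]), 0.0, rng)
        coded = code_genotypes(GenotypeBlock(g, ["s"]))
        c = null_correlation(coded, adr=True)
        assert c[0, 1] == pytest.approx(0.8165, abs=0.02)

    def test_stacked_matrix_is_rank_deficient(self, null_cohort):
        _, coded, _ = null_cohort
        lam = np.linalg.eigvalsh(null_correlation(coded, adr=True))
        assert lam.min() <= 1e-8

    def test_degenerate_column_gets_identity_row(self):
        g = np.array([[0, 1], [1, 0], [0, 1], [1, 2]], dtype=np.int8)
        coded = code_genotypes(GenotypeBlock(g, ["a", "b"]))
        c = null_correlation(coded, adr=True)
        # recessive coding of SNP a is constant -> independent coordinate
        j = 4  # recessive segment, first SNP
        assert c[j, j] == 1.0
        off = np.delete(c[j], j)
        np.testing.assert_allclose(off, 0.0)


class TestSampler:
    def test_marginal_variances(self, rng):
        model = NullModel(np.eye(4))
        draws = model.sample(50_000, rng)
        np.testing.assert_allclose(draws.var(axis=0), 1.0, atol=0.03)

    def test_seed_determinism(self):
        model = NullModel(np.eye(3))
        a = draw_null_statistics(model, 100, 42)
        b = draw_null_statistics(model, 100, 42)
        np.testing.assert_array_equal(a, b)

    def test_perfect_correlation_degenerates(self, rng):
        model = NullModel(np.ones((3, 3)))
        draws = model.sample(50, rng)
        np.testing.assert_allclose(draws, np.repeat(draws[:, :1], 3, axis=1),
                                   atol=1e-10)

    def test_covariance_recovers_target(self, rng):
        c = np.array([[1.0, -0.6], [-0.6, 1.0]])
        draws = NullModel(c).sample(100_000, rng)
        assert np.corrcoef(draws.T)[0, 1] == pytest.approx(-0.6, abs=0.02)


class TestStatistics:
    @pytest.mark.parametrize(
        "z,t,expected",
        [
            ([3, -1, 0], 6, 9.0),
            ([3, -1, 0], 0, 10.0),
            ([1, 1, -1], 4, 0.0),
        ],
    )
    def test_ss_threshold_values(self, z, t, expected):
        assert ss_threshold_stat(np.array(z, float), t) == pytest.approx(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ss_threshold_stat(np.array([1.0]), -1)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=12).map(np.array),
        st.floats(0, 30),
        st.floats(0, 30),
    )
    def test_ss_nonincreasing_in_threshold(self, z, t1, t2):
        lo, hi = sorted([t1, t2])
        assert ss_threshold_stat(z, hi) <= ss_threshold_stat(z, lo) + 1e-9

    def test_max_chisq(self):
        assert max_chisq_stat(np.array([1.0, -2.0, 0.5])) == pytest.approx(4.0)
        assert max_chisq_stat(np.array([3.0])) == pytest.approx(9.0)
        z = np.array([0.3, -1.7, 0.9])
        assert max_chisq_stat(z) == max_chisq_stat(-z)


class TestMcPvalue:
    def test_boundaries_and_median(self, rng):
        null = np.arange(999, dtype=float)
        assert mc_pvalue(1e9, null) == pytest.approx(1 / 1000)
        assert mc_pvalue(-1.0, null) == pytest.approx(1.0)
        assert mc_pvalue(499.0, null) == pytest.approx(0.501)

    def test_empty_null_sample(self):
        with pytest.raises(ValueError):
            mc_pvalue(1.0, np.array([]))


class TestSimulationBlockP:
    def test_m1_reduction_to_univariate_p(self, rng):
        g = draw_genotype_matrix(400, np.array([0.4]), 0.0, rng)
        y = np.concatenate([np.ones(200, np.int8), np.zeros(200, np.int8)])
        rng.shuffle(y)
        coded = code_genotypes(GenotypeBlock(g, ["s"]))
        univ = adr_statistics(y, coded)
        model = NullModel(null_correlation(coded, adr=False))
        res = simulation_block_p("v_minp", univ, model, B=10_000, seed=rng)
        assert res.p_value == pytest.approx(univ.p_add[0], abs=0.02)

    def test_all_methods_coincide_for_m1_t0(self, rng, null_cohort):
        block, coded, y = null_cohort
        sub = code_genotypes(
            GenotypeBlock(block.genotypes[:, :1], [block.snp_ids[0]])
        )
        univ = adr_statistics(y, sub)
        model = NullModel(null_correlation(sub, adr=False))
        draws = model.sample(5000, rng)
        ps = {
            m: simulation_block_p(m, univ, model, t=0.0, null_draws=draws).p_value
            for m in ("ss_t", "v_ss", "v_minp")
        }
        assert len(set(ps.values())) == 1

    def test_dimension_mismatch_is_error(self, null_cohort, rng):
        _, coded, y = null_cohort
        univ = adr_statistics(y, coded)
        model = NullModel(null_correlation(coded, adr=False))
        with pytest.raises(ValueError, match="dimension"):
            simulation_block_p("v_ss", univ, model, adr=True, seed=rng)

    def test_unknown_method(self, null_cohort, rng):
        _, coded, y = null_cohort
        univ = adr_statistics(y, coded)
        model = NullModel(null_correlation(coded, adr=False))
        with pytest.raises(ValueError, match="unknown"):
            simulation_block_p("bogus", univ, model, seed=rng)

    def test_adr_reduces_to_plain_when_extra_segments_silent(self, rng):
        # force dominant/recessive z to 0 and their correlation blocks to
        # identity: the ADR SS-T must equal the plain SS-T
        from blocktest.univariate import UnivariateResults

        z = np.array([1.2, -0.7, 2.6])
        m = 3
        univ = UnivariateResults(
            z_add=z, z_dom=np.zeros(m), z_rec=np.zeros(m),
            p_add=np.ones(m), p_dom=np.ones(m), p_rec=np.ones(m),
            defined_add=np.ones(m, bool), defined_dom=np.zeros(m, bool),
            defined_rec=np.zeros(m, bool),
        )
        corr_a = np.eye(m)
        corr_adr = np.eye(3 * m)
        corr_adr[:m, :m] = corr_a
        model_a = NullModel(corr_a)
        model_adr = NullModel(corr_adr)
        # same seed: the first m columns of the ADR draws replicate the plain
        # draws only in distribution, so compare observed statistics instead
        res_a = simulation_block_p("ss_t", univ, model_a, t=2.0, seed=1)
        res_adr = simulation_block_p("ss_t", univ, model_adr, t=2.0, seed=1, adr=True)
        assert res_a.statistic == pytest.approx(res_adr.statistic)

    def test_null_pvalues_valid_and_calibrated(self, rng):
        # v_ss p-values are uniform (continuous statistic); ss_6 p-values are
        # sub-uniform with an atom at 1 (the statistic has an atom at 0), so
        # only their lower tail is calibrated
        c = np.full((4, 4), 0.6)
        np.fill_diagonal(c, 1.0)
        model = NullModel(c)
        obs = model.sample(500, rng)
        nulls = model.sample(200 * 500, rng).reshape(500, 200, 4)

        def pvals(t):
            z2n, z2o = nulls**2, obs**2
            sn = (z2n * (z2n >= t)).sum(axis=2)
            so = (z2o * (z2o >= t)).sum(axis=1)
            return (1 + (sn >= so[:, None]).sum(axis=1)) / 201

        p_vss = pvals(0.0)
        assert 0.42 < p_vss.mean() < 0.58
        p_ss6 = pvals(6.0)
        for alpha in (0.05, 0.1, 0.2):
            assert (p_ss6 <= alpha).mean() <= alpha + 2 * np.sqrt(alpha / 500)
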