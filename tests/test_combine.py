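import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from blocktest.combine import (
    bonferroni_p,
    effective_tests,
    gates_p,
    pc_test,
    pvalue_correlation,
    simes_p,
    spc_test,
)

pvec_strategy = st.lists(
    st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=30
).map(np.array)


class TestBonferroniSimes:
    @pytest.mark.parametrize(
        "pvec,expected",
        [
            ([0.01, 0.5, 0.9], 0.03),
            ([1.0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], 1.0),
        ],
    )
    def test_bonferroni_values(self, pvec, expected):
        assert bonferroni_p(np.array(pvec)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pvec,expected",
        [
            ([0.01, 0.02, 0.03], 0.03),
            ([0.04, 0.5], 0.08),
            ([0.37], 0.37),
        ],
    )
    def test_simes_values(self, pvec, expected):
        assert simes_p(np.array(pvec)) == pytest.approx(expected)

    def test_empty_vector_is_an_error(self):
        with pytest.raises(ValueError):
            bonferroni_p(np.array([]))
        with pytest.raises(ValueError):
            simes_p(np.array([]))

    @settings(derandomize=True, max_examples=60)
    @given(pvec_strategy)
    def test_simes_never_exceeds_bonferroni(self, pvec):
        assert simes_p(pvec) <= bonferroni_p(pvec) + 1e-12


class TestEffectiveTests:
    @pytest.mark.parametrize(
        "corr,expected",
        [
            (np.eye(5), 5.0),
            (np.array([[1.0, 1.0], [1.0, 1.0]]), 1.0),
            (np.array([[1.0, 0.6], [0.6, 1.0]]), 1.4),
        ],
    )
    def test_hand_eigendecompositions(self, corr, expected):
        assert effective_tests(corr) == pytest.approx(expected)

    def test_permutation_invariance(self, rng):
        z = rng.standard_normal((200, 6))
        c = np.corrcoef(z, rowvar=False)
        perm = rng.permutation(6)
        assert effective_tests(c[np.ix_(perm, perm)]) == pytest.approx(
            effective_tests(c)
        )

    def test_rejects_non_unit_diagonal(self):
        with pytest.raises(ValueError):
            effective_tests(np.array([[2.0, 0.0], [0.0, 2.0]]))


class TestGates:
    def test_reduces_to_simes_for_independent_snps(self):
        pvec = np.array([0.01, 0.2, 0.7, 0.04])
        assert gates_p(pvec, np.eye(4)) == pytest.approx(simes_p(pvec))

    def test_single_snp_returns_its_p(self):
        assert gates_p(np.array([0.123]), np.eye(1)) == pytest.approx(0.123)

    def test_perfectly_correlated_duplicates_count_once(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert gates_p(np.array([0.01, 0.01]), c) == pytest.approx(0.01)

    def test_pvalue_transform_matches_monte_carlo(self, rng):
        r = 0.8
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=300_000)
        p = 2 * stats.norm.sf(np.abs(z))
        emp = np.corrcoef(p.T)[0, 1]
        table = pvalue_correlation(np.array([[1.0, r], [r, 1.0]]))[0, 1]
        assert table == pytest.approx(emp, abs=0.01)

    def test_direct_transform_is_smaller_p(self):
        # using the statistic correlation as-is overstates dependence
        pvec = np.array([0.01, 0.2, 0.4])
        c = np.full((3, 3), 0.7)
        np.fill_diagonal(c, 1.0)
        assert gates_p(pvec, c, transform="direct") <= gates_p(pvec, c)


class TestPc:
    def test_full_rank_k_equals_quadratic_form(self, rng):
        a = rng.standard_normal((50, 4))
        c = np.corrcoef(a, rowvar=False)
        z = rng.standard_normal(4)
        q, _ = pc_test(z, c, k=4)
        assert q == pytest.approx(z @ np.linalg.solve(c, z), abs=1e-8)

    def test_zero_statistics(self):
        q, p = pc_test(np.zeros(5), np.eye(5), k=3)
        assert q == 0.0 and p == 1.0

    def test_null_mean_is_chisq_k(self, rng):
        c = np.full((6, 6), 0.5)
        np.fill_diagonal(c, 1.0)
        lam, vec = np.linalg.eigh(c)
        draws = rng.standard_normal((10_000, 6)) @ (vec * np.sqrt(lam)).T
        qs = [pc_test(d, c, k=3)[0] for d in draws[:2000]]
        assert np.mean(qs) == pytest.approx(3.0, abs=0.15)

    def test_k_exceeding_rank_is_error_unless_clamped(self):
        c = np.ones((2, 2))
        with pytest.raises(ValueError, match="retained"):
            pc_test(np.zeros(2), c, k=2)
        q, p = pc_test(np.zeros(2), c, k=2, clamp_k=True)
        assert p == 1.0


class TestSpc:
    def test_composition_of_simes_and_pc(self, rng):
        pvec = np.array([0.03, 0.4, 0.9])
        z = rng.standard_normal(3)
        c = np.eye(3)
        expected = simes_p(
            np.array([simes_p(pvec), pc_test(z, c, k=3)[1]])
        )
        assert spc_test(pvec, z, c) == pytest.approx(expected)

    def test_two_component_simes_arithmetic(self):
        assert simes_p(np.array([0.02, 0.5])) == pytest.approx(0.04)
        assert simes_p(np.array([0.5, 0.01])) == pytest.approx(0.02)
        assert simes_p(np.array([1.0, 1.0])) == pytest.approx(1.0)
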