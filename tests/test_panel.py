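import numpy as np
import pytest
from scipy import stats

from blocktest.genotypes import GenotypeBlock
from blocktest.panel import (
    DegenerateTableError,
    _bvn_cdf,
    estimate_pcc,
    infer_ld_blocks,
    make_synthetic_panel,
    pcc_matrix,
    resample_cohort_genotypes,
)
from blocktest.simulate import draw_genotype_matrix


class TestBvnCdf:
    def test_against_scipy_mvn(self):
        for rho in (-0.9, -0.3, 0.0, 0.5, 0.95):
            mv = stats.multivariate_normal(cov=[[1, rho], [rho, 1]])
            for h, k in [(-1.2, 0.3), (0.0, 0.0), (2.0, -1.5)]:
                assert _bvn_cdf(np.array(h), np.array(k), rho) == pytest.approx(
                    mv.cdf([h, k]), abs=1e-8
                )

    def test_infinite_limits(self):
        assert _bvn_cdf(np.array(np.inf), np.array(0.0), 0.7) == pytest.approx(0.5)
        assert _bvn_cdf(np.array(-np.inf), np.array(0.0), 0.7) == 0.0


class TestEstimatePcc:
    def test_identical_columns_hit_upper_boundary(self, rng):
        g = draw_genotype_matrix(2000, np.array([0.3]), 0.0, rng)[:, 0]
        assert estimate_pcc(g, g) >= 0.99

    def test_symmetric_in_arguments(self, rng):
        g = draw_genotype_matrix(3000, np.array([0.3, 0.5]), 0.6, rng)
        assert estimate_pcc(g[:, 0], g[:, 1]) == pytest.approx(
            estimate_pcc(g[:, 1], g[:, 0]), abs=1e-4
        )

    def test_independent_columns_near_zero(self, rng):
        g = draw_genotype_matrix(50_000, np.array([0.2, 0.4]), 0.0, rng)
        assert abs(estimate_pcc(g[:, 0], g[:, 1])) < 0.02

    def test_monomorphic_column_rejected(self):
        with pytest.raises(DegenerateTableError):
            estimate_pcc(np.zeros(100, int), np.tile([0, 1, 2], 34)[:100])


class TestInferBlocks:
    def test_two_groups_of_duplicated_columns(self, rng):
        a = draw_genotype_matrix(800, np.array([0.3]), 0.0, rng)[:, 0]
        b = draw_genotype_matrix(800, np.array([0.4]), 0.0, rng)[:, 0]
        g = np.column_stack([a, a, b, b]).astype(np.int8)
        panel = GenotypeBlock(g, ["a1", "a2", "b1", "b2"])
        part = infer_ld_blocks(panel, 0.64)
        assert part.n_blocks == 2
        labels = dict(zip(part.snp_ids, part.block_ids))
        assert labels["a1"] == labels["a2"] != labels["b1"] == labels["b2"]

    def test_single_snp_panel(self, rng):
        g = draw_genotype_matrix(100, np.array([0.3]), 0.0, rng)
        part = infer_ld_blocks(GenotypeBlock(g, ["s"]))
        assert part.n_blocks == 1

    def test_zero_threshold_merges_everything(self, rng):
        g = draw_genotype_matrix(500, np.full(5, 0.3), 0.0, rng)
        part = infer_ld_blocks(GenotypeBlock(g, [f"s{i}" for i in range(5)]), 0.0)
        assert part.n_blocks == 1

    def test_invariant_to_snp_relabeling(self, rng):
        panel, _ = make_synthetic_panel([3, 3], [0.9, 0.9], [0.3, 0.3], 2000, rng)
        part1 = infer_ld_blocks(panel)
        renamed = GenotypeBlock(panel.genotypes, [f"x{i}" for i in range(6)])
        part2 = infer_ld_blocks(renamed)
        np.testing.assert_array_equal(part1.block_ids, part2.block_ids)


class TestSyntheticPanel:
    def test_truth_partition_shapes(self, rng):
        panel, truth = make_synthetic_panel(
            [5, 10, 15], [0.9, 0.9, 0.9], [0.3, 0.3, 0.3], 1000, rng
        )
        assert panel.n_snps == 30 and len(truth.block_ids) == 30
        assert truth.n_blocks == 3

    def test_determinism_contract(self):
        p1, _ = make_synthetic_panel([4], [0.8], [0.3], 500, 9)
        p2, _ = make_synthetic_panel([4], [0.8], [0.3], 500, 9)
        p3, _ = make_synthetic_panel([4], [0.8], [0.3], 500, 10)
        np.testing.assert_array_equal(p1.genotypes, p2.genotypes)
        assert not np.array_equal(p1.genotypes, p3.genotypes)


class TestResampling:
    def test_rows_are_panel_members(self, rng):
        panel, _ = make_synthetic_panel([4], [0.8], [0.3], 50, rng)
        cohort = resample_cohort_genotypes(panel, 200, rng)
        panel_rows = {tuple(r) for r in panel.genotypes}
        assert all(tuple(r) in panel_rows for r in cohort.genotypes)

    def test_preserves_frequencies_and_ld(self, rng):
        panel, _ = make_synthetic_panel([3], [0.8], [0.3], 4000, rng)
        cohort = resample_cohort_genotypes(panel, 20_000, rng)
        np.testing.assert_allclose(
            cohort.counted_allele_freq(), panel.counted_allele_freq(), atol=0.02
        )
        pcc_panel = estimate_pcc(panel.genotypes[:, 0], panel.genotypes[:, 1])
        pcc_cohort = estimate_pcc(cohort.genotypes[:, 0], cohort.genotypes[:, 1])
        assert pcc_cohort == pytest.approx(pcc_panel, abs=0.05)
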