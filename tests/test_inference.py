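"""Hypothesis-testing battery: exactness, gating logic, decision rules."""

import numpy as np
import pytest
from scipy import stats

from _oracles import wilcoxon_exact_enumeration
from volrely import (
    ci_overlap_significant,
    fisher_z_test,
    ks_normality,
    paired_location_test,
    variance_f_test,
    wilcoxon_signed_rank,
)


class TestKSNormality:
    def test_rejects_exponential(self, rng):
        res = ks_normality(rng.exponential(1.0, 5000))
        assert res.significant  # normality rejected

    def test_accepts_most_gaussian_samples(self, rng):
        # parameters estimated from the sample make the naive KS conservative
        rejections = sum(ks_normality(rng.normal(0, 1, 200)).significant for _ in range(100))
        assert rejections <= 5

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestWilcoxon:
    def test_all_positive_differences_n8(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 9.0), np.zeros(8))
        assert res.p_value == pytest.approx(2 / 256)  # both one-sided tails doubled
        assert res.statistic == 36.0

    def test_matches_sign_flip_enumeration(self, rng):
        for n in range(3, 11):
            for _ in range(5):
                a = rng.normal(0.3, 1.0, n)
                b = rng.normal(0.0, 1.0, n)
                p_impl = wilcoxon_signed_rank(a, b).p_value
                p_enum = wilcoxon_exact_enumeration(a, b)
                assert p_impl == pytest.approx(p_enum, abs=1e-12), f"n={n}"

    def test_handles_ties_and_zeros(self, rng):
        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 4.0])
        b = np.array([1.0, 1.0, 1.0, 2.0, 3.0, 3.0, 5.0, 4.0])  # zeros dropped, ties midranked
        p_impl = wilcoxon_signed_rank(a, b).p_value
        p_enum = wilcoxon_exact_enumeration(a, b)
        assert p_impl == pytest.approx(p_enum, abs=1e-12)

    def test_all_zero_differences(self):
        res = wilcoxon_signed_rank(np.ones(6), np.ones(6))
        assert res.p_value == 1.0 and not res.significant

    def test_large_sample_normal_approximation_close_to_exact_at_25(self, rng):
        a = rng.normal(0.5, 1.0, 25)
        b = rng.normal(0.0, 1.0, 25)
        exact = wilcoxon_signed_rank(a, b).p_value  # n=25 still exact
        approx = wilcoxon_signed_rank(
            np.concatenate([a, [a.mean()]]), np.concatenate([b, [b.mean() - 0.1]])
        ).p_value  # n=26 uses the normal path; sanity: in (0, 1)
        assert 0 < approx < 1
        assert 0 < exact < 1


class TestPairedLocationTest:
    def test_identical_samples_no_evidence(self):
        res = paired_location_test(np.arange(10.0), np.arange(10.0))
        assert res.p_value == 1.0 and not res.significant

    def test_gate_chooses_t_for_gaussian(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.1, 1, 100)
        assert paired_location_test(a, b).test_name == "paired_t"

    def test_gate_chooses_wilcoxon_for_skewed(self, rng):
        a = rng.exponential(1.0, 200)
        b = rng.exponential(1.2, 200)
        assert paired_location_test(a, b).test_name == "wilcoxon"

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_location_test([1, 2, 3, 4, 5], [1, 2, 3, 4])


class TestVarianceFTest:
    def test_identical_samples(self, rng):
        a = rng.normal(0, 1, 30)
        res = variance_f_test(a, a)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_p_matches_f_cdf_closed_form(self, rng):
        a = rng.normal(0, 2, 40)
        b = rng.normal(0, 1, 35)
        res = variance_f_test(a, b)
        f = np.var(a, ddof=1) / np.var(b, ddof=1)
        p = 2 * min(stats.f.cdf(f, 39, 34), 1 - stats.f.cdf(f, 39, 34))
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_detects_fourfold_variance_ratio(self, rng):
        hits = sum(
            variance_f_test(rng.normal(0, 2, 50), rng.normal(0, 1, 50)).significant
            for _ in range(100)
        )
        assert hits > 95

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            variance_f_test([1, 1, 1], [1, 2, 3])


class TestFisherZ:
    def test_equal_correlations(self):
        res = fisher_z_test(0.5, 50, 0.5, 50)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_closed_form(self):
        res = fisher_z_test(0.9, 103, 0.3, 103)
        z = (np.arctanh(0.9) - np.arctanh(0.3)) / np.sqrt(1 / 100 + 1 / 100)
        p = 2 * stats.norm.sf(abs(z))
        assert res.statistic == pytest.approx(z, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.significant

    def test_antisymmetric_in_arguments(self):
        r1 = fisher_z_test(0.8, 60, 0.4, 40)
        r2 = fisher_z_test(0.4, 40, 0.8, 60)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_test(1.0, 50, 0.5, 50)


class TestCIOverlapRule:
    def test_identical_estimates_not_significant(self):
        assert not ci_overlap_significant(0.9, (0.8, 0.95), 0.9, (0.8, 0.95))

    def test_disjoint_case(self):
        assert ci_overlap_significant(0.985, (0.973, 0.992), 0.893, (0.813, 0.939))

    def test_one_estimate_inside_other_interval(self):
        assert not ci_overlap_significant(0.990, (0.944, 0.998), 0.976, (0.869, 0.996))

    def test_asymmetric_variant(self):
        # B's estimate is inside A's CI but A's estimate is outside B's CI
        assert not ci_overlap_significant(0.90, (0.70, 0.99), 0.80, (0.75, 0.85))
        assert ci_overlap_significant(0.90, (0.70, 0.99), 0.80, (0.75, 0.85), symmetric=False)

    def test_malformed_inputs(self):
        with pytest.raises(ValueError, match="low > high"):
            ci_overlap_significant(0.9, (0.95, 0.85), 0.8, (0.7, 0.9))
        with pytest.raises(ValueError, match="outside its own"):
            ci_overlap_significant(0.99, (0.7, 0.9), 0.8, (0.7, 0.9))
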