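"""Bland-Altman agreement, ICC(1), gated comparisons, grading concordance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctgrad import (
    ValidationError,
    bland_altman,
    correlation_and_see,
    grading_concordance,
    icc_oneway,
    paired_comparison,
    subgroup_error_comparison,
)


class TestBlandAltman:
    def test_echo_versus_catheter_limits_of_agreement(self):
        # differences with mean -11.5 and sample SD exactly 16.4
        diffs = np.array([-11.5 - 16.4, -11.5, -11.5 + 16.4])
        res = bland_altman(diffs, np.zeros(3))
        assert res.mean_diff == pytest.approx(-11.5)
        assert res.sd_diff == pytest.approx(16.4)
        assert round(res.loa_lower, 1) == -43.6
        assert round(res.loa_upper, 1) == 20.6

    def test_identity_gives_zero_bias_and_zero_loa(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x)
        assert res.mean_diff == 0 and res.sd_diff == 0
        assert res.loa_lower == 0 and res.loa_upper == 0

    def test_hand_computed_example(self):
        res = bland_altman(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_lower == pytest.approx(0.04)
        assert res.loa_upper == pytest.approx(3.96)

    def test_length_mismatch_and_small_n_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0, 2.0], [1.0])
        with pytest.raises(ValidationError):
            bland_altman([1.0], [1.0])

    @given(c=st.floats(-50, 50), seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_constant_offset_recovered_exactly(self, c, seed):
        x = np.random.default_rng(seed).normal(50, 20, 12)
        res = bland_altman(x + c, x)
        assert res.mean_diff == pytest.approx(c, abs=1e-9)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-9)


class TestICCOneWay:
    def test_identical_raters_give_one(self):
        m = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc_oneway(m).icc == pytest.approx(1.0)

    def test_hand_anova_value(self):
        # MSB = 8, MSW = 0.5 -> (8-0.5)/(8+0.5) = 0.882...
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc_oneway(m).icc == pytest.approx(7.5 / 8.5)

    def test_all_equal_is_undefined_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = icc_oneway(np.full((4, 3), 2.0))
        assert np.isnan(res.icc)

    def test_incomplete_matrix_rejected(self):
        m = np.array([[1.0, np.nan], [3.0, 4.0]])
        with pytest.raises(ValidationError):
            icc_oneway(m)

    @given(
        n=st.integers(3, 12),
        k=st.integers(2, 5),
        seed=st.integers(0, 10_000),
        shift=st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_shift_invariance(self, n, k, seed, shift):
        m = np.random.default_rng(seed).normal(0, 5, (n, k))
        res = icc_oneway(m)
        assert -1.0 / (k - 1) - 1e-12 <= res.icc <= 1.0 + 1e-12
        assert icc_oneway(m + shift).icc == pytest.approx(res.icc, abs=1e-8)

    def test_matches_independent_implementation(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(17)
        m = rng.normal(50, 10, (10, 3)) + rng.normal(0, 5, (10, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 3),
                "rater": np.tile(np.arange(3), 10),
                "score": m.ravel(),
            }
        )
        reference = pg.intraclass_corr(df, "subject", "rater", "score")
        icc1 = reference.loc[reference["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert icc_oneway(m).icc == pytest.approx(icc1, abs=1e-9)


class TestPairedComparison:
    def test_normal_differences_take_t_branch(self):
        rng = np.random.default_rng(0)
        y = rng.normal(50, 10, 30)
        x = y + rng.normal(2, 3, 30)
        res = paired_comparison(x, y)
        assert res.test_used == "t"

    def test_skewed_differences_take_wilcoxon_branch(self):
        rng = np.random.default_rng(1)
        y = rng.normal(50, 5, 40)
        x = y + rng.lognormal(1.0, 1.2, 40)  # heavily right-skewed differences
        res = paired_comparison(x, y)
        assert res.test_used == "wilcoxon"

    def test_equal_vectors_give_zero_mean_difference(self):
        x = np.arange(1.0, 11.0)
        with pytest.warns(UserWarning, match="zero"):
            res = paired_comparison(x, x)
        assert res.mean_diff == 0.0
        assert res.p == 1.0


class TestSubgroupComparison:
    def test_mann_whitney_exact_p_by_full_enumeration(self):
        """Exact two-sided Mann-Whitney p for {1,2,3} vs {4,5,6}: enumerate
        all C(6,3)=20 assignments of ranks to group A and count U's at least
        as extreme as the observed (here the most extreme possible)."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        pooled = a + b
        u_obs = sum(x < y for x in a for y in b)  # 9, the maximum
        count = 0
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u = sum(x < y for x in ga for y in gb)
            # two-sided: as extreme in either direction
            if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
                count += 1
        p_enumerated = count / 20
        assert p_enumerated == pytest.approx(0.1)

        res = subgroup_error_comparison(
            np.array(a + b), np.array([0, 0, 0, 1, 1, 1]), test="mann_whitney"
        )
        assert res.test_used == "mann_whitney"
        assert res.p == pytest.approx(p_enumerated)
        assert res.group_means == (2.0, 5.0)

    def test_identical_groups_have_zero_mean_difference(self):
        e = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array([0, 0, 0, 1, 1, 1])
        res = subgroup_error_comparison(e, g)
        assert res.group_means[0] == res.group_means[1]

    def test_label_values_do_not_matter(self):
        rng = np.random.default_rng(3)
        e = rng.normal(0, 10, 30)
        g = rng.integers(0, 2, 30)
        a = subgroup_error_comparison(e, g)
        b = subgroup_error_comparison(e, np.where(g == 0, "f", "m"))
        assert a.p == pytest.approx(b.p)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            subgroup_error_comparison([1.0, 2.0, 3.0], [0, 1, 1])


class TestGradingConcordance:
    def test_percentage_arithmetic_77_of_84(self):
        # 80 patients below threshold on both, 4 discordant one way, 3 the
        # other; only the cross-tabulation counts should matter
        a = np.array([50.0] * 77 + [70.0] * 4 + [50.0] * 3)
        b = np.array([50.0] * 77 + [50.0] * 4 + [70.0] * 3)
        res = grading_concordance(a, b)
        assert res.n_concordant == 77
        assert res.n_a_only == 4
        assert res.n_b_only == 3
        assert res.pct_concordant == 91.7

    def test_identical_methods_fully_concordant(self):
        a = np.array([10.0, 70.0, 64.0])
        res = grading_concordance(a, a)
        assert res.pct_concordant == 100.0

    def test_constructed_discordance(self):
        res = grading_concordance([70.0, 50.0], [50.0, 70.0])
        assert (res.n_concordant, res.n_a_only, res.n_b_only) == (0, 1, 1)

    def test_symmetric_in_method_order(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(20, 110, 50)
        b = rng.uniform(20, 110, 50)
        assert (
            grading_concordance(a, b).pct_concordant
            == grading_concordance(b, a).pct_concordant
        )


class TestCorrelationAndSee:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 11.0)
        res = correlation_and_see(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.see == pytest.approx(0.0, abs=1e-9)

    def test_zero_correlation_three_points(self):
        res = correlation_and_see([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            correlation_and_see([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
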