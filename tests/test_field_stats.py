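"""ANOVA, assumption checks, letter displays, correlations, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst
from scipy import stats as sps

import soiltrial as st
from soiltrial.errors import DegenerateDataError
from soiltrial.fieldstats import stars_for

from .oracles import (anova_f_loops, least_squares_closed_form,
                      pearson_r_loops)


class TestAnova:
    def test_toy_dataset_gives_f_three_halves(self):
        res = st.one_way_anova([1, 2, 3, 2, 3, 4], list("aaabbb"))
        assert res.F == pytest.approx(1.5, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p == pytest.approx(float(sps.f.sf(1.5, 1, 4)), abs=1e-12)

    def test_identical_groups_give_zero_f(self):
        res = st.one_way_anova([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], list("aaabbb"))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_location_invariance(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat(list("abcde"), 6)
        a = st.one_way_anova(values, groups)
        b = st.one_way_anova(values + 1234.5, groups)
        assert b.F == pytest.approx(a.F, rel=1e-9)
        assert b.p == pytest.approx(a.p, rel=1e-6)

    def test_agrees_with_scipy(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat(list("abcde"), 6)
        mine = st.one_way_anova(values, groups)
        ref = sps.f_oneway(*(values[groups == g] for g in "abcde"))
        assert mine.F == pytest.approx(float(ref.statistic), rel=1e-10)
        assert mine.p == pytest.approx(float(ref.pvalue), rel=1e-8)

    @given(hst.lists(hst.floats(-100, 100), min_size=10, max_size=30))
    def test_sum_of_squares_identity(self, values):
        values = np.asarray(values)
        groups = np.array((["a", "b", "c"] * 10)[: len(values)])
        if min((groups == g).sum() for g in "abc") < 2:
            return
        if np.ptp(values) == 0:
            return
        res = st.one_way_anova(values, groups)
        sst = float(((values - values.mean()) ** 2).sum())
        assert res.ss_between + res.ss_within == pytest.approx(sst, rel=1e-8, abs=1e-8)

    def test_matches_loop_oracle(self, rng):
        groups = [rng.normal(loc=m, size=6).tolist() for m in (0, 1, 3)]
        flat = [v for g in groups for v in g]
        labels = np.repeat(list("abc"), 6)
        f, dfb, dfw = anova_f_loops(groups)
        res = st.one_way_anova(flat, labels)
        assert res.F == pytest.approx(f, rel=1e-10)
        assert (res.df_between, res.df_within) == (dfb, dfw)

    def test_zero_within_variance_flags_infinite_f(self):
        res = st.one_way_anova([1, 1, 1, 2, 2, 2], list("aaabbb"))
        assert res.degenerate and np.isinf(res.F) and res.p == 0.0

    def test_undersized_group_rejected(self):
        with pytest.raises(DegenerateDataError, match="fewer than 2"):
            st.one_way_anova([1, 2, 3], ["a", "a", "b"])


class TestAssumptions:
    def test_well_behaved_gaussian_groups_pass(self, rng):
        values = rng.normal(size=150)
        groups = np.repeat(list("abcde"), 30)
        rep = st.check_assumptions(values, groups)
        assert rep.normality_ok and rep.homogeneity_ok

    def test_gross_variance_heterogeneity_detected(self, rng):
        a = rng.normal(scale=1.0, size=30)
        b = rng.normal(scale=5.0, size=30)
        rep = st.check_assumptions(np.concatenate([a, b]),
                                   ["a"] * 30 + ["b"] * 30)
        assert not rep.homogeneity_ok

    def test_constant_group_flagged_not_assessable(self):
        rep = st.check_assumptions([1.0, 1.0, 1.0, 1.0, 2.0, 3.0],
                                   list("aaabbb"))
        row = rep.shapiro.set_index("group").loc["a"]
        assert not row["assessable"] and np.isnan(row["p"])

    def test_tiny_group_flagged_not_assessable(self):
        rep = st.check_assumptions([1.0, 2.0, 1.5, 2.5], list("aabb"))
        assert not rep.shapiro["assessable"].any()


class TestLetters:
    def test_hugely_separated_groups_get_distinct_letters(self, rng):
        values = np.concatenate([rng.normal(0, 0.01, 6),
                                 rng.normal(10, 0.01, 6),
                                 rng.normal(20, 0.01, 6)])
        groups = np.repeat(["lo", "mid", "hi"], 6)
        res = st.pairwise_letters(values, groups)
        assert sorted(res.letters.values()) == ["a", "b", "c"]
        assert res.letters["hi"] == "a"  # highest mean gets 'a'

    def test_identically_drawn_groups_share_a_letter(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat(list("abcde"), 6)
        res = st.pairwise_letters(values, groups)
        assert set(res.letters.values()) == {"a"}

    def test_two_group_dichotomy(self, rng):
        values = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(5, 0.1, 6)])
        res = st.pairwise_letters(values, np.repeat(["x", "y"], 6))
        assert res.letters["y"] == "a" and res.letters["x"] == "b"

    @pytest.mark.parametrize("method", ["tukey", "lsd"])
    def test_letter_sharing_encodes_nonsignificance(self, method, rng):
        """Core CLD contract: two groups share a letter iff their pairwise
        comparison is nonsignificant — checked on noisy overlapping data."""
        for trial in range(5):
            means = rng.uniform(0, 4, size=5)
            values = np.concatenate([rng.normal(m, 1.0, 6) for m in means])
            groups = np.repeat(list("abcde"), 6)
            res = st.pairwise_letters(values, groups, method=method)
            for i, gi in enumerate("abcde"):
                for gj in "abcde"[i + 1:]:
                    shares = set(res.letters[gi]) & set(res.letters[gj])
                    significant = res.pairwise_p.loc[gi, gj] < res.alpha
                    assert bool(shares) == (not significant), (
                        trial, gi, gj, res.letters)

    def test_tukey_matches_scipy_pvalues(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat(list("abcde"), 6)
        res = st.pairwise_letters(values, groups)
        ref = sps.tukey_hsd(*(values[groups == g] for g in "abcde"))
        for i, gi in enumerate("abcde"):
            for j, gj in enumerate("abcde"):
                if i < j:
                    assert res.pairwise_p.loc[gi, gj] == pytest.approx(
                        float(ref.pvalue[i, j]), abs=1e-12)


class TestPearson:
    def test_exact_line_gives_unit_correlation(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        frame["y"] = 2 * frame.x + 1
        res = st.pearson_matrix(frame)
        assert res.r.loc["x", "y"] == pytest.approx(1.0)

    def test_sign_reflection(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 5.0]})
        frame["neg"] = -frame.x
        res = st.pearson_matrix(frame)
        assert res.r.loc["x", "neg"] == pytest.approx(-1.0)

    def test_five_point_fixture_matches_quotient_oracle(self, rng):
        x = rng.uniform(size=5)
        y = rng.uniform(size=5)
        res = st.pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        assert res.r.loc["x", "y"] == pytest.approx(pearson_r_loops(x, y), abs=1e-12)

    def test_symmetry_unit_diagonal_and_bounds(self, default_trial):
        res = st.pearson_matrix(default_trial.soil, list(st.INDICATOR_NAMES))
        r = res.r.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1 + 1e-12).all()

    def test_constant_variable_flagged_not_raised(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        res = st.pearson_matrix(frame)
        assert res.constant_variables == ["c"]
        assert np.isnan(res.r.loc["x", "c"])

    @pytest.mark.parametrize("p,label", [
        (0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.07, ""), (np.nan, ""),
    ])
    def test_star_threshold_map(self, p, label):
        assert stars_for(p) == label


class TestRegression:
    def test_noiseless_line_recovered_exactly(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = st.fit_linear(x, 3 * x - 1)
        assert fit.slope == pytest.approx(3.0, abs=1e-12)
        assert fit.intercept == pytest.approx(-1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_four_point_fixture_matches_normal_equations(self, rng):
        x = rng.uniform(size=4)
        y = rng.uniform(size=4)
        fit = st.fit_linear(x, y)
        slope, intercept, r2 = least_squares_closed_form(x.tolist(), y.tolist())
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_r_squared_equals_squared_pearson_r(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        fit = st.fit_linear(x, y)
        assert fit.r_squared == pytest.approx(pearson_r_loops(x, y) ** 2, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDataError, match="constant"):
            st.fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
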