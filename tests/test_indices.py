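"""Min-max scoring, PCA-communality weighting and the composite SQI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

import soiltrial as st
from soiltrial.errors import AlignmentError, DegenerateDataError
from soiltrial.indices import (compute_sqi, pca_communalities, score_indicators,
                               sqi_pipeline, weights_from_communalities)

from .oracles import communalities_bruteforce, minmax_scores, weighted_sum_loops


def soil_frame(columns: dict) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    base = {"plot_id": [f"p{i}" for i in range(n)],
            "treatment": (["CK", "CF", "M1", "M2", "M3"] * n)[:n]}
    return pd.DataFrame({**base, **columns})


class TestScoring:
    def test_bound_cases(self):
        sm = score_indicators(soil_frame({"organic_matter": [5.0, 10.0, 20.0]}))
        col = sm.scores["organic_matter"]
        assert col.iloc[0] == 0.0 and col.iloc[2] == 1.0

    def test_midpoint_scores_half_either_direction(self):
        frame = soil_frame({"organic_matter": [5.0, 10.0, 15.0],
                            "bulk_density": [1.2, 1.3, 1.4]})
        sm = score_indicators(frame)
        assert sm.scores["organic_matter"].iloc[1] == pytest.approx(0.5)
        assert sm.scores["bulk_density"].iloc[1] == pytest.approx(0.5)

    def test_less_is_better_reverses(self):
        sm = score_indicators(soil_frame({"bulk_density": [1.2, 1.3, 1.4]}))
        assert sm.scores["bulk_density"].tolist() == pytest.approx([1.0, 0.5, 0.0])

    def test_matches_loop_oracle(self, default_trial):
        sm = score_indicators(default_trial)
        for name in st.INDICATOR_NAMES:
            direction = sm.directions[name]
            expected = minmax_scores(default_trial.soil[name].tolist(), direction)
            np.testing.assert_allclose(sm.scores[name], expected, atol=1e-12)

    def test_data_derived_bounds_touch_zero_and_one(self, default_trial):
        sm = score_indicators(default_trial)
        assert (sm.scores.min(axis=0) == 0.0).all()
        assert (sm.scores.max(axis=0) == 1.0).all()

    def test_fixed_bounds_are_recorded_and_used(self):
        sm = score_indicators(soil_frame({"ph": [6.0, 7.0, 8.0]}),
                              bounds={"ph": (5.0, 9.0)})
        assert sm.bounds_used.loc["ph"].tolist() == [5.0, 9.0]
        assert sm.scores["ph"].iloc[1] == pytest.approx(0.5)  # less-is-better midpoint

    def test_constant_indicator_is_an_error_or_dropped(self):
        frame = soil_frame({"ph": [7.0, 7.0, 7.0], "total_n": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateDataError, match="ph"):
            score_indicators(frame)
        sm = score_indicators(frame, drop_degenerate=True)
        assert sm.dropped == ["ph"] and list(sm.scores.columns) == ["total_n"]

    @given(a=hst.floats(0.1, 50), b=hst.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        values = [1.0, 2.5, 4.0, 7.5]
        sm1 = score_indicators(soil_frame({"total_n": values}))
        sm2 = score_indicators(soil_frame({"total_n": [a * v + b for v in values]}))
        np.testing.assert_allclose(sm1.scores["total_n"], sm2.scores["total_n"],
                                   atol=1e-9)


class TestCommunalities:
    def test_perfectly_correlated_pair_has_unit_communalities(self):
        frame = soil_frame({"total_n": [1.0, 2.0, 3.0, 4.0],
                            "organic_matter": [2.0, 4.0, 6.0, 8.0]})
        comm = pca_communalities(frame, retention=1)
        np.testing.assert_allclose(comm, [1.0, 1.0], atol=1e-10)

    def test_retaining_all_components_gives_unit_communalities(self, default_trial):
        comm = pca_communalities(default_trial.soil, retention="all")
        np.testing.assert_allclose(comm, np.ones(12), atol=1e-8)

    def test_matches_bruteforce_eigendecomposition(self, rng):
        x = rng.normal(size=(5, 3))
        frame = soil_frame({"total_n": x[:, 0], "available_p": x[:, 1],
                            "urease": x[:, 2]})
        comm = pca_communalities(frame, retention="kaiser")
        expected = communalities_bruteforce(x)
        np.testing.assert_allclose(comm.to_numpy(), expected, atol=1e-8)

    def test_communalities_bounded(self, default_trial):
        comm = pca_communalities(default_trial.soil)
        assert ((comm >= 0) & (comm <= 1)).all()

    def test_cumulative_variance_retention(self, default_trial):
        strict = pca_communalities(default_trial.soil, retention=0.99)
        loose = pca_communalities(default_trial.soil, retention=0.5)
        assert strict.attrs["n_retained"] >= loose.attrs["n_retained"]

    def test_too_few_plots_rejected(self):
        with pytest.raises(DegenerateDataError, match="3 plots"):
            pca_communalities(soil_frame({"total_n": [1.0, 2.0],
                                          "ph": [6.5, 7.0]}))

    def test_constant_indicator_rejected(self):
        frame = soil_frame({"total_n": [1.0, 2.0, 3.0], "ph": [7.0, 7.0, 7.0]})
        with pytest.raises(DegenerateDataError, match="ph"):
            pca_communalities(frame)


class TestWeights:
    def test_equal_communalities_give_uniform_weights(self):
        c = pd.Series(0.8, index=[f"i{k}" for k in range(12)])
        w = weights_from_communalities(c).weights
        np.testing.assert_allclose(w, np.full(12, 1 / 12), atol=1e-12)

    def test_ratio_arithmetic(self):
        w = weights_from_communalities(pd.Series({"a": 0.9, "b": 0.3})).weights
        assert w["a"] == pytest.approx(0.75) and w["b"] == pytest.approx(0.25)

    @given(hst.lists(hst.floats(0.01, 1.0), min_size=2, max_size=12))
    def test_weights_sum_to_one(self, values):
        c = pd.Series(values, index=[f"i{k}" for k in range(len(values))])
        assert weights_from_communalities(c).weights.sum() == pytest.approx(1.0, abs=1e-12)

    @given(hst.floats(0.1, 100.0))
    def test_weights_invariant_to_communality_scale(self, k):
        c = pd.Series({"a": 0.9, "b": 0.3, "c": 0.6})
        w1 = weights_from_communalities(c).weights
        w2 = weights_from_communalities(c * k).weights
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_all_zero_communalities_rejected(self):
        with pytest.raises(DegenerateDataError, match="zero"):
            weights_from_communalities(pd.Series({"a": 0.0, "b": 0.0}))


class TestSQI:
    def test_unit_scores_give_unit_sqi(self):
        frame = soil_frame({"total_n": [1.0, 2.0, 3.0, 4.0],
                            "available_p": [10.0, 20.0, 30.0, 40.0]})
        sm = score_indicators(frame)
        sm.scores.loc[:, :] = 1.0
        w = weights_from_communalities(pd.Series({"total_n": 0.5, "available_p": 0.5}))
        res = compute_sqi(sm, w)
        np.testing.assert_allclose(res.per_plot["sqi"], 1.0)

    def test_uniform_weights_reduce_to_row_mean(self, default_trial):
        sm = score_indicators(default_trial)
        w = weights_from_communalities(
            pd.Series(1.0, index=sm.scores.columns))
        res = compute_sqi(sm, w)
        np.testing.assert_allclose(res.per_plot["sqi"],
                                   sm.scores.mean(axis=1), atol=1e-12)

    def test_matches_dot_product_oracle(self, rng):
        frame = soil_frame({"total_n": rng.uniform(0.5, 2, 4),
                            "ph": rng.uniform(6, 8, 4),
                            "urease": rng.uniform(10, 40, 4)})
        sm = score_indicators(frame)
        comm = pca_communalities(frame)
        w = weights_from_communalities(comm)
        res = compute_sqi(sm, w)
        expected = weighted_sum_loops(
            sm.scores.to_numpy().tolist(),
            w.weights.reindex(sm.scores.columns).tolist())
        np.testing.assert_allclose(res.per_plot["sqi"], expected, atol=1e-12)

    def test_indicator_mismatch_lists_symmetric_difference(self, default_trial):
        sm = score_indicators(default_trial)
        w = weights_from_communalities(pd.Series({"total_n": 0.5, "bogus": 0.5}))
        with pytest.raises(AlignmentError, match="bogus"):
            compute_sqi(sm, w)

    def test_sqi_bounded_and_treatment_means_inside_member_range(self, default_trial):
        res = sqi_pipeline(default_trial)
        assert ((res.per_plot["sqi"] >= 0) & (res.per_plot["sqi"] <= 1)).all()
        for _, row in res.per_treatment.iterrows():
            members = res.per_plot[res.per_plot.treatment == row.treatment]["sqi"]
            assert members.min() <= row["mean"] <= members.max()

    def test_rescaled_output_is_display_only(self, default_trial):
        res = sqi_pipeline(default_trial)
        scaled = res.rescaled(10.0)
        np.testing.assert_allclose(scaled["sqi"], res.per_plot["sqi"] * 10)
        with pytest.raises(DegenerateDataError):
            res.rescaled(0.0)

    def test_monotone_in_more_is_better_indicator(self, default_trial):
        """With fixed bounds and fixed weights, raising a more-is-better
        value never lowers that plot's SQI."""
        sm = score_indicators(default_trial)
        bounds = {name: (row.xmin, row.xmax)
                  for name, row in sm.bounds_used.iterrows()}
        w = weights_from_communalities(
            pca_communalities(default_trial.soil))
        base = compute_sqi(sm, w).per_plot["sqi"]

        bumped = default_trial.soil.copy()
        target = bumped.loc[7, "organic_matter"]
        span = bounds["organic_matter"][1] - bounds["organic_matter"][0]
        bumped.loc[7, "organic_matter"] = target + 0.1 * span
        sm2 = score_indicators(bumped, bounds=bounds)
        after = compute_sqi(sm2, w).per_plot["sqi"]
        assert after.iloc[7] >= base.iloc[7] - 1e-12
        others = np.delete(np.arange(len(base)), 7)
        np.testing.assert_allclose(after.iloc[others], base.iloc[others], atol=1e-12)


def test_full_chain_matches_loop_reimplementation(rng):
    """Whole scoring → weighting → SQI chain vs an explicit-loop
    reimplementation on a small table (≤ 6 indicators, ≤ 6 plots)."""
    names = ["bulk_density", "ph", "organic_matter", "total_n", "urease"]
    frame = soil_frame({
        "bulk_density": rng.uniform(1.1, 1.5, 6),
        "ph": rng.uniform(6.5, 7.5, 6),
        "organic_matter": rng.uniform(10, 26, 6),
        "total_n": rng.uniform(0.5, 1.3, 6),
        "urease": rng.uniform(10, 35, 6),
    })
    result = sqi_pipeline(frame)

    directions = st.default_direction_map()
    score_cols = [minmax_scores(frame[n].tolist(), directions[n]) for n in names]
    scores = list(map(list, zip(*score_cols)))
    comm = communalities_bruteforce(frame[names].to_numpy())
    weights = [c / sum(comm) for c in comm]
    expected = weighted_sum_loops(scores, weights)
    np.testing.assert_allclose(result.per_plot["sqi"], expected, atol=1e-10)
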