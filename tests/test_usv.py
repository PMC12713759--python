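"""USV protocol: filtering, temporal metrics, macro F1, forest ensemble."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import macro_f1_bruteforce
from sickstate.simulate import UsvSimConfig, generate_usv
from sickstate.usv import balanced_subsample_ensemble, filter_calls, macro_f1, temporal_metrics


class TestFilter:
    def test_strictly_shorter_than_5ms_removed(self):
        t = pd.DataFrame({"duration_ms": [3.0, 5.0, 7.0], "f": [1, 2, 3]})
        out = filter_calls(t)
        assert list(out["duration_ms"]) == [5.0, 7.0]

    def test_identity_when_all_long_enough(self):
        t = pd.DataFrame({"duration_ms": [5.0, 9.0]})
        pd.testing.assert_frame_equal(filter_calls(t), t)

    def test_empty_table_stays_empty(self):
        t = pd.DataFrame({"duration_ms": []})
        assert filter_calls(t).empty

    def test_missing_duration_column_errors(self):
        with pytest.raises(ValueError, match="duration"):
            filter_calls(pd.DataFrame({"x": [1]}))


class TestTemporalMetrics:
    def test_hand_computed_lag_differences(self):
        onsets = [0.0, 0.1, 0.25, 0.5]
        out = temporal_metrics(onsets, [10.0] * 4)
        np.testing.assert_allclose(
            out["onset_diff_lag1"], [0.1, 0.15, 0.25, np.nan], atol=1e-12
        )
        np.testing.assert_allclose(
            out["onset_diff_lag2"], [0.25, 0.4, np.nan, np.nan], atol=1e-12
        )
        np.testing.assert_allclose(
            out["onset_diff_lag3"], [0.5, np.nan, np.nan, np.nan], atol=1e-12
        )

    def test_zero_onset_ratio_missing(self):
        out = temporal_metrics([0.0, 1.0], [10.0, 20.0])
        assert np.isnan(out["duration_onset_ratio"][0])
        assert out["duration_onset_ratio"][1] == pytest.approx(20.0)

    def test_single_call_all_lags_missing(self):
        out = temporal_metrics([2.0], [8.0])
        assert out[["onset_diff_lag1", "onset_diff_lag2", "onset_diff_lag3"]].isna().all().all()

    def test_unsorted_onsets_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            temporal_metrics([1.0, 0.5], [1.0, 1.0])


class TestMacroF1:
    def test_perfect_prediction(self):
        per, macro = macro_f1([0, 1, 2, 0], [0, 1, 2, 0])
        assert macro == 1.0 and (per == 1.0).all()

    def test_hand_computed_example(self):
        # class "a": TP=2, FP=1, FN=2 -> precision 2/3, recall 1/2, F1 = 4/7
        y_true = ["a", "a", "a", "a", "b", "b", "b"]
        y_pred = ["a", "a", "b", "b", "a", "b", "b"]
        per, _ = macro_f1(y_true, y_pred)
        assert per["a"] == pytest.approx(4 / 7)

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(100):
            n = rng.integers(5, 40)
            k = rng.integers(2, 5)
            y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            _, macro = macro_f1(y_true, y_pred)
            assert macro == macro_f1_bruteforce(y_true, y_pred)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=1, max_size=30))
    def test_bounded_and_oracle_exact(self, pairs):
        y_true = [a for a, _ in pairs]
        y_pred = [b for _, b in pairs]
        _, macro = macro_f1(y_true, y_pred)
        assert 0.0 <= macro <= 1.0
        assert macro == macro_f1_bruteforce(y_true, y_pred)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            macro_f1([0, 1], [0])


@pytest.fixture(scope="module")
def usv_table():
    cfg = UsvSimConfig(
        n_calls_per_condition=60, conditions=("Saline", "LPS", "pIC"), seed=31
    )
    return filter_calls(generate_usv(cfg))


class TestEnsemble:
    FAST_RF = {"n_estimators": 30, "max_depth": 10}

    def test_separable_features_score_high(self):
        from sickstate.simulate import default_class_shifts

        conds = ("Saline", "LPS", "pIC")
        cfg = UsvSimConfig(
            n_calls_per_condition=60,
            conditions=conds,
            class_shift_map=default_class_shifts(conds, 31, effect=5.0),
            seed=31,
        )
        table = filter_calls(generate_usv(cfg))
        rep = balanced_subsample_ensemble(
            table, n_forests=3, subsample_per_class=40, rf_params=self.FAST_RF, seed=1
        )
        assert rep.f1_mean >= 0.95
        np.testing.assert_allclose(rep.confusion.sum(axis=1), 1.0, atol=1e-8)

    def test_shuffled_two_class_near_half(self):
        cfg = UsvSimConfig(
            n_calls_per_condition=200, conditions=("Saline", "LPS"), seed=17
        )
        table = filter_calls(generate_usv(cfg))
        rep = balanced_subsample_ensemble(
            table, n_forests=8, subsample_per_class=150,
            rf_params=self.FAST_RF, shuffle=True, seed=2,
        )
        se = rep.f1_sd / np.sqrt(len(rep.per_iteration_f1))
        assert abs(rep.f1_mean - 0.5) <= max(3 * se, 0.05)

    def test_oversized_subsample_names_the_class(self, usv_table):
        with pytest.raises(ValueError, match="subsample_per_class"):
            balanced_subsample_ensemble(usv_table, subsample_per_class=10_000, seed=0)

    def test_deterministic_under_seed(self, usv_table):
        kw = dict(n_forests=2, subsample_per_class=30, rf_params=self.FAST_RF, seed=5)
        a = balanced_subsample_ensemble(usv_table, **kw)
        b = balanced_subsample_ensemble(usv_table, **kw)
        assert a.per_iteration_f1 == b.per_iteration_f1
        pd.testing.assert_frame_equal(a.confusion, b.confusion)

    def test_missing_label_column_rejected(self, usv_table):
        with pytest.raises(ValueError, match="label column"):
            balanced_subsample_ensemble(usv_table.drop(columns="condition"), seed=0)
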