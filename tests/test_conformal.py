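"""Conformal core: p-values, regions, aggregation, splits, validity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from thyscreen import (AggregatedConformalClassifier, GaussianSpec, SplitPlan,
                       assign_region, fit_aggregated, gen_gaussian, p_value,
                       split_data)


def brute_force_p_value(cal_scores, test_score):
    """Independent oracle: literal rank counting."""
    count = 0
    for s in cal_scores:
        if s >= test_score:
            count += 1
    return (count + 1) / (len(cal_scores) + 1)


class TestPValue:
    @pytest.mark.parametrize("scores,test,expected", [
        ([0.1, 0.2, 0.9], 0.5, 0.5),       # one score >= 0.5 -> 2/4
        ([0.3, 0.4, 0.5], 0.1, 1.0),       # below all -> maximal conformity
        ([0.1, 0.2, 0.3], 0.9, 1 / 4),     # above all -> 1/(n+1)
        ([0.5], 0.5, 1.0),                 # tie counts as >=
    ])
    def test_counting_examples(self, scores, test, expected):
        assert p_value(scores, test) == pytest.approx(expected)

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            p_value([], 0.5)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(1, 40))
            cal = np.round(rng.random(n), 2)  # rounding forces ties
            test = float(np.round(rng.random(), 2))
            assert p_value(cal, test) == brute_force_p_value(list(cal), test)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
           st.floats(0, 1, allow_nan=False))
    def test_matches_brute_force_property(self, cal, test):
        assert p_value(cal, test) == brute_force_p_value(cal, test)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
           st.floats(0, 1, allow_nan=False))
    def test_in_half_open_unit_interval(self, cal, test):
        p = p_value(cal, test)
        assert 0 < p <= 1


class TestAssignRegion:
    @pytest.mark.parametrize("pa,pi,sl,region,dec", [
        (0.5, 0.5, 0.1, "both", 0.0),
        (0.05, 0.5, 0.1, "inactive", -0.45),
        (0.5, 0.05, 0.1, "active", 0.45),
        (0.05, 0.05, 0.1, "empty", 0.0),
        (0.1, 0.1, 0.1, "empty", 0.0),      # inclusion is strict: p > sl
    ])
    def test_region_mapping(self, pa, pi, sl, region, dec):
        got_region, got_dec = assign_region(pa, pi, sl)
        assert got_region == region
        assert got_dec == pytest.approx(dec)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1),
           st.floats(0.01, 0.99))
    def test_total_function_and_decidability_range(self, pa, pi, sl):
        region, dec = assign_region(pa, pi, sl)
        assert region in {"active", "inactive", "both", "empty"}
        assert -1 <= dec <= 1


class TestSplits:
    def test_stratified_validation_proportions(self):
        X = np.zeros((100, 3))
        y = np.array(["active"] * 10 + ["inactive"] * 90, dtype=object)
        _, X_val, _, y_val = split_data(X, y, SplitPlan(base_seed=1))
        assert len(y_val) == 20
        assert (y_val == "active").sum() == 2

    def test_deterministic_given_seed(self):
        X, y = gen_gaussian(GaussianSpec(n=100, active_fraction=0.5, seed=0))
        a = split_data(X, y, SplitPlan(base_seed=7))
        b = split_data(X, y, SplitPlan(base_seed=7))
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array(["active"] * 10, dtype=object)
        with pytest.raises(ValueError, match="both classes"):
            split_data(X, y)

    def test_bad_plan_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(proper_training_fraction=0.7, calibration_fraction=0.4)


class TestAggregate:
    def test_member_count_and_bookkeeping(self, small_model):
        model, _, _ = small_model
        assert len(model.members_) == 10
        for m in model.members_:
            for c in model.classes_:
                assert len(m.calibration_scores[c]) >= 1
                assert np.all(np.isfinite(m.calibration_scores[c]))

    def test_calibration_class_sizes_match_split(self, gaussian_dataset):
        X, y = gaussian_dataset
        model = AggregatedConformalClassifier(
            n_models=1, n_estimators=20, random_state=0).fit(X, y)
        n_act = int((y == "active").sum())
        expected = int(round(0.3 * n_act))
        got = len(model.members_[0].calibration_scores["active"])
        assert abs(got - expected) <= 1

    def test_members_use_different_partitions(self, gaussian_dataset):
        X, y = gaussian_dataset
        model = AggregatedConformalClassifier(
            n_models=20, n_estimators=10, random_state=0).fit(X, y)
        signatures = {tuple(np.round(m.calibration_scores["active"], 6))
                      for m in model.members_}
        assert len(signatures) >= 19  # distinct 70/30 splits w.h.p.

    def test_median_of_single_member_is_identity(self, gaussian_dataset):
        X, y = gaussian_dataset
        model = AggregatedConformalClassifier(
            n_models=1, n_estimators=30, random_state=2).fit(X, y)
        p_agg = model.predict_p(X[:20])
        p_member = model.members_[0].p_values(X[:20])
        np.testing.assert_array_equal(p_agg, p_member)

    def test_even_member_median_is_midpoint(self):
        # {0.2 x25, 0.4 x25} -> 0.3
        stack = np.array([0.2] * 25 + [0.4] * 25)
        assert np.median(stack) == pytest.approx(0.3)

    def test_member_order_invariance(self, small_model):
        model, X_val, _ = small_model
        before = model.predict_p(X_val[:30])
        rng = np.random.default_rng(0)
        try:
            rng.shuffle(model.members_)
            after = model.predict_p(X_val[:30])
        finally:
            model.members_.sort(key=lambda m: m.seed)
        np.testing.assert_array_equal(before, after)

    def test_deterministic_refit(self, gaussian_dataset):
        X, y = gaussian_dataset
        kwargs = dict(n_models=5, n_estimators=30, random_state=9)
        a = AggregatedConformalClassifier(**kwargs).fit(X, y)
        b = AggregatedConformalClassifier(**kwargs).fit(X, y)
        np.testing.assert_array_equal(a.predict_p(X[:50]), b.predict_p(X[:50]))

    def test_fit_aggregated_returns_untouched_validation(self,
                                                         gaussian_dataset):
        X, y = gaussian_dataset
        model, X_val, y_val = fit_aggregated(
            X, y, SplitPlan(base_seed=1), n_models=3, n_estimators=20)
        assert len(y_val) == round(0.2 * len(y))
        # validation class balance preserved within rounding
        frac = (y_val == "active").mean()
        assert abs(frac - 0.3) < 0.02

    def test_requires_two_classes(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        y = np.array(["active"] * 40, dtype=object)
        with pytest.raises(ValueError, match="2 classes"):
            AggregatedConformalClassifier(n_models=2).fit(X, y)

    def test_tiny_class_warns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        y = np.array(["active"] * 4 + ["inactive"] * 46, dtype=object)
        with pytest.warns(UserWarning, match="only 4"):
            AggregatedConformalClassifier(
                n_models=2, n_estimators=10).fit(X, y)

    def test_sklearn_clone_and_get_params(self):
        from sklearn.base import clone
        est = AggregatedConformalClassifier(n_models=7, random_state=3)
        cloned = clone(est)
        assert cloned.get_params()["n_models"] == 7

    def test_feature_count_mismatch_rejected(self, small_model):
        model, X_val, _ = small_model
        with pytest.raises(ValueError):
            model.predict_p(X_val[:, :3])


class TestConformalGuarantees:
    def test_per_class_error_rate_bounded(self, small_model):
        """Central CP property: P(true label excluded) <= sl + margin."""
        model, X_val, y_val = small_model
        p = model.predict_p(X_val)
        for sl in (0.05, 0.1, 0.2, 0.3):
            for k, cls in enumerate(model.classes_):
                mask = y_val == cls
                n = int(mask.sum())
                errors = int((p[mask, k] <= sl).sum())
                bound = stats.binom.ppf(0.99, n, sl)
                assert errors <= bound, (cls, sl, errors, bound)

    def test_prediction_sets_nested_in_sl(self, small_model):
        model, X_val, _ = small_model
        p = model.predict_p(X_val)
        sls = [0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3]
        # monotonicity: label inclusion only shrinks as sl grows
        stacks = [p > sl for sl in sls]
        for lo, hi in zip(stacks[:-1], stacks[1:]):
            assert np.all(lo >= hi)

    def test_true_class_p_values_dominate_uniform(self):
        """Single-ICP p-values under the true class are superuniform up to
        calibration discreteness (grid check at alpha = 0.01)."""
        X, y = gen_gaussian(GaussianSpec(n=1600, active_fraction=0.5,
                                         class_separation=1.0, seed=21))
        model, X_val, y_val = fit_aggregated(
            X, y, SplitPlan(base_seed=4), n_models=1, n_estimators=100)
        p = model.predict_p(X_val)
        for k, cls in enumerate(model.classes_):
            mask = y_val == cls
            pv = p[mask, k]
            n = int(mask.sum())
            n_cal = len(model.members_[0].calibration_scores[cls])
            for t in np.arange(0.05, 1.0, 0.05):
                observed = int((pv <= t).sum())
                bound = stats.binom.ppf(0.9995, n, t + 1.0 / (n_cal + 1))
                assert observed <= bound, (cls, t, observed, bound)
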