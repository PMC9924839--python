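import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ecglvh as e
from ecglvh.models import (
    BackpropNetLVH,
    BpnConfig,
    DecisionTreeLVH,
    KMeansLVH,
    ModelReport,
    SplitPlan,
    balanced_cohort,
    node_entropy,
    split_cases,
)


class TestNodeEntropy:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 0.0), (0.5, 1.0)])
    def test_endpoints_exact(self, p, expected):
        assert node_entropy(p) == expected

    def test_quarter_fraction(self):
        assert node_entropy(0.25) == pytest.approx(0.8112781244591328, abs=1e-12)

    @given(p=st.floats(0, 1, allow_nan=False))
    def test_symmetric_and_bounded(self, p):
        h = node_entropy(p)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(node_entropy(1.0 - p), abs=1e-12)

    @pytest.mark.parametrize("p", [-0.1, 1.1, float("nan")])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            node_entropy(p)


class TestModelReport:
    def test_metric_identities_from_counts(self):
        r = ModelReport(tp=29, fn=1, tn=28, fp=2)
        assert r.sensitivity == pytest.approx(0.9667, abs=5e-5)
        assert r.specificity == pytest.approx(0.9333, abs=5e-5)
        assert r.precision == pytest.approx(0.9355, abs=5e-5)
        assert r.accuracy == pytest.approx(0.95)

    def test_perfect_predictions(self):
        r = ModelReport.from_predictions([1, 0, 1, 0], [1, 0, 1, 0])
        assert (r.accuracy, r.precision, r.sensitivity, r.specificity) == (1, 1, 1, 1)

    def test_all_positive_predictor_on_balanced_test(self):
        r = ModelReport.from_predictions([1, 1, 0, 0], [1, 1, 1, 1])
        assert r.sensitivity == 1.0 and r.specificity == 0.0 and r.accuracy == 0.5

    def test_zero_denominator_is_nan_not_zero(self):
        r = ModelReport.from_predictions([0, 0], [0, 0])
        assert math.isnan(r.precision) and math.isnan(r.sensitivity)

    @given(
        counts=st.tuples(*[st.integers(0, 40)] * 4).filter(lambda c: sum(c) > 0)
    )
    def test_identities_hold_on_any_counts(self, counts):
        tp, fp, tn, fn = counts
        r = ModelReport(tp=tp, fp=fp, tn=tn, fn=fn)
        assert r.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))


class TestBalancedCohort:
    def test_majority_downsampled_to_minority(self):
        df = pd.DataFrame({"label": [True] * 17 + [False] * 78, "x": range(95)})
        out = balanced_cohort(df, seed=0)
        assert int(out["label"].sum()) == 17
        assert int((~out["label"]).sum()) == 17

    def test_already_balanced_returned_unchanged(self):
        df = pd.DataFrame({"label": [True, False] * 5, "x": range(10)})
        out = balanced_cohort(df, seed=0)
        assert sorted(out["x"]) == list(range(10))

    def test_same_seed_same_subset(self):
        df = pd.DataFrame({"label": [True] * 10 + [False] * 50, "x": range(60)})
        a = balanced_cohort(df, seed=42)
        b = balanced_cohort(df, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_cohort(pd.DataFrame({"label": [True] * 4}), seed=0)


class TestSplitCases:
    def test_grouped_split_keeps_subjects_on_one_side(self):
        rows = []
        for subj in range(40):
            for beat in range(8):
                rows.append({"subject_id": f"s{subj}", "label": subj % 2 == 0, "x": 0.0})
        df = pd.DataFrame(rows)
        train, test = split_cases(df, SplitPlan(seed=1), group_col="subject_id")
        assert not set(train["subject_id"]) & set(test["subject_id"])

    def test_seven_three_proportions(self):
        df = pd.DataFrame({"label": [True, False] * 50, "x": range(100)})
        train, test = split_cases(df, SplitPlan(seed=0))
        assert len(train) == 70 and len(test) == 30


def _blob_data(n=60, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n, 2))
    b = rng.normal(sep, 1.0, size=(n, 2))
    X = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2"])
    y = np.array([False] * n + [True] * n)
    return X, y


class TestDecisionTree:
    def test_separable_1d_picks_depth_one(self):
        X = pd.DataFrame({"f": np.r_[np.zeros(30), np.ones(30)]})
        y = np.array([False] * 30 + [True] * 30)
        res = DecisionTreeLVH(X, y, seed=0).fit()
        assert res.depth_ == 1
        assert res.depth_scores_.iloc[0]["cv_accuracy"] == 1.0

    def test_xor_needs_depth_at_least_two(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.uniform(-1, 1, size=(400, 2)), columns=["a", "b"])
        y = (X["a"] > 0) ^ (X["b"] > 0)
        res = DecisionTreeLVH(X, y.to_numpy(), seed=0).fit()
        assert res.depth_ >= 2

    def test_noise_labels_near_chance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(200, 4)))
        y = rng.uniform(size=200) < 0.5
        res = DecisionTreeLVH(X, y, seed=0).fit(depth_range=range(1, 8))
        best = res.depth_scores_["cv_accuracy"].max()
        assert abs(best - 0.5) < 0.15

    def test_single_class_training_rejected(self):
        X = pd.DataFrame({"f": np.arange(30.0)})
        with pytest.raises(ValueError, match="class"):
            DecisionTreeLVH(X, np.ones(30, dtype=bool), seed=0).fit()

    def test_summary_mentions_depth(self):
        X, y = _blob_data(30)
        res = DecisionTreeLVH(X, y, seed=0).fit(depth_range=range(1, 4))
        assert "Chosen depth" in res.summary()


class TestKMeans:
    def test_separated_blobs_reach_perfect_training_accuracy(self):
        X, y = _blob_data(50, sep=8.0)
        res = KMeansLVH(X, y, seed=0).fit(k=2)
        assert res.evaluate(X, y).accuracy == 1.0

    def test_unrelated_labels_near_class_prior(self):
        rng = np.random.default_rng(5)
        X, _ = _blob_data(100, sep=8.0, seed=5)
        y = rng.uniform(size=200) < 0.5
        acc = KMeansLVH(X, y, seed=0).fit(k=2).evaluate(X, y).accuracy
        assert acc < 0.65

    def test_k_one_predicts_majority(self):
        X, _ = _blob_data(20)
        y = np.array([True] * 25 + [False] * 15)
        res = KMeansLVH(X, y, seed=0).fit(k=1)
        assert res.predict(X).all()

    def test_k_larger_than_n_rejected(self):
        X, y = _blob_data(3)
        with pytest.raises(ValueError):
            KMeansLVH(X, y, seed=0).fit(k=100)


class TestBackpropNet:
    def test_strong_effect_recovered_on_held_out_data(self):
        X, y = e.synth_feature_table(n_per_class=150, effect_size=3.0, seed=9)
        df = X.copy()
        df["label"] = y
        train, test = split_cases(df, SplitPlan(seed=9))
        res = BackpropNetLVH.from_dataframe(train, config=BpnConfig(seed=9)).fit()
        rep = res.evaluate(test[list(e.FEATURE_NAMES)], test["label"])
        assert rep.accuracy >= 0.95

    def test_cv_diagnostics_reported(self):
        X, y = e.synth_feature_table(n_per_class=60, effect_size=3.0, seed=2)
        cfg = BpnConfig(epochs=60, seed=2)
        res = BackpropNetLVH(X, y, config=cfg).fit(cv=SplitPlan(cv_folds=5, seed=2))
        assert len(res.diagnostics["cv_accuracies"]) == 5
        assert "CV accuracy" in res.summary()

    def test_seeded_fit_is_deterministic(self):
        X, y = e.synth_feature_table(n_per_class=50, effect_size=2.0, seed=3)
        cfg = BpnConfig(epochs=40, seed=3)
        a = BackpropNetLVH(X, y, config=cfg).fit()
        b = BackpropNetLVH(X, y, config=cfg).fit()
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        for wa, wb in zip(a.estimator.coefs_, b.estimator.coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_architecture_matches_config(self):
        X, y = e.synth_feature_table(n_per_class=30, effect_size=2.0, seed=4)
        res = BackpropNetLVH(X, y, config=BpnConfig(epochs=10, seed=0)).fit()
        assert [w.shape for w in res.estimator.coefs_] == [(24, 26), (26, 1)]
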