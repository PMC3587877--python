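import json

import numpy as np
import pandas as pd
import pytest

from anesdepth import classify
from anesdepth.core import AnesthesiaState
from anesdepth.features import FeatureMatrix


def _gaussian_feature_matrix(rng, means, n_per_class=30, n_noise=0, sd=0.5):
    """Four well-separated classes on one informative feature."""
    rows, labels = [], []
    for state, mu in zip(AnesthesiaState, means):
        x = mu + sd * rng.standard_normal(n_per_class)
        cols = {"f0": x}
        for j in range(n_noise):
            cols[f"noise{j}"] = rng.standard_normal(n_per_class)
        rows.append(pd.DataFrame(cols))
        labels.extend([state.value] * n_per_class)
    return FeatureMatrix(pd.concat(rows, ignore_index=True), np.array(labels))


class TestFitPredict:
    def test_separated_classes_classified_perfectly(self, rng):
        fm = _gaussian_feature_matrix(rng, [0.0, 10.0, 20.0, 30.0])
        model = classify.fit(fm, ["f0"])
        pred = classify.predict(model, fm)
        assert (pred == fm.labels).all()

    def test_fit_is_deterministic(self, rng):
        fm = _gaussian_feature_matrix(rng, [0.0, 5.0, 10.0, 15.0])
        a = classify.fit(fm, ["f0"]).to_json()
        b = classify.fit(fm, ["f0"]).to_json()
        assert a == b

    def test_unknown_feature_lists_valid_names(self, rng):
        fm = _gaussian_feature_matrix(rng, [0.0, 5.0, 10.0, 15.0])
        with pytest.raises(KeyError, match="f0"):
            classify.fit(fm, ["bogus"])

    def test_missing_class_rejected(self, rng):
        fm = _gaussian_feature_matrix(rng, [0.0, 5.0, 10.0, 15.0])
        keep = fm.labels != AnesthesiaState.DEEP.value
        reduced = FeatureMatrix(
            fm.data.loc[keep].reset_index(drop=True), fm.labels[keep]
        )
        with pytest.raises(ValueError, match="DEEP"):
            classify.fit(reduced, ["f0"])

    def test_empty_subset_rejected(self, rng):
        fm = _gaussian_feature_matrix(rng, [0.0, 5.0, 10.0, 15.0])
        with pytest.raises(ValueError, match="non-empty"):
            classify.fit(fm, [])

    def test_posterior_tie_breaks_toward_shallower_state(self, rng):
        """Identical class-conditionals give equal posteriors everywhere;
        the fixed class order resolves them toward AWAKE."""
        n = 40
        x = np.tile(rng.standard_normal(n), 4)
        labels = np.repeat([s.value for s in AnesthesiaState], n)
        fm = FeatureMatrix(pd.DataFrame({"f0": x}), labels)
        model = classify.fit(fm, ["f0"])
        pred = classify.predict(model, fm)
        assert (pred == AnesthesiaState.AWAKE.value).all()

    def test_sentinel_rows_excluded(self, rng):
        fm = _gaussian_feature_matrix(rng, [0.0, 10.0, 20.0, 30.0])
        fm.data.iloc[0, 0] = np.nan
        model = classify.fit(fm, ["f0"])
        assert len(classify.predict(model, fm)) == len(fm) - 1

    def test_model_serializes_to_json(self, rng):
        fm = _gaussian_feature_matrix(rng, [0.0, 5.0, 10.0, 15.0])
        payload = json.loads(classify.fit(fm, ["f0"]).to_json())
        assert payload["subset"] == ["f0"]
        assert len(payload["means"]) == 4
        assert len(payload["covariances"]) == 4


class TestEvaluate:
    def test_all_correct(self):
        y = np.repeat([0, 1, 2, 3], 5)
        report = classify.evaluate(y, y)
        assert report.accuracy == 100.0
        assert all(v == 1.0 for v in report.sensitivity.values())
        assert all(v == 1.0 for v in report.specificity.values())

    def test_two_class_total_swap(self):
        y_true = np.repeat([0, 1], 10)
        y_pred = np.repeat([1, 0], 10)
        report = classify.evaluate(y_true, y_pred)
        assert report.accuracy == 0.0
        assert report.specificity["AWAKE"] == 0.0
        assert report.specificity["LIGHT"] == 0.0

    def test_hand_computed_confusion_metrics(self):
        """4-class example checked against a by-hand spreadsheet calculation."""
        cm = np.array(
            [[8, 1, 1, 0], [0, 9, 1, 0], [1, 0, 8, 1], [0, 0, 2, 8]]
        )
        y_true, y_pred = [], []
        for i in range(4):
            for j in range(4):
                y_true.extend([i] * cm[i, j])
                y_pred.extend([j] * cm[i, j])
        report = classify.evaluate(np.array(y_true), np.array(y_pred))
        np.testing.assert_array_equal(report.confusion, cm)
        assert report.accuracy == pytest.approx(100 * 33 / 40)
        assert report.sensitivity["AWAKE"] == pytest.approx(0.8)
        assert report.sensitivity["LIGHT"] == pytest.approx(0.9)
        assert report.specificity["AWAKE"] == pytest.approx(29 / 30)
        assert report.specificity["DEEP"] == pytest.approx(26 / 30)
        assert report.specificity["ISOELECTRIC"] == pytest.approx(29 / 30)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            classify.evaluate(np.array([0, 1]), np.array([0]))
        with pytest.raises(ValueError):
            classify.evaluate(np.array([]), np.array([]))


class TestCrossValidation:
    def test_reproducible_under_seed(self, rng):
        fm = _gaussian_feature_matrix(rng, [0.0, 2.0, 4.0, 6.0], n_noise=2)
        a = classify.cross_validated_report(fm, ["f0", "noise0"], seed=3)
        b = classify.cross_validated_report(fm, ["f0", "noise0"], seed=3)
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_accuracy_invariant_under_column_permutation(self, rng):
        fm = _gaussian_feature_matrix(rng, [0.0, 2.0, 4.0, 6.0], n_noise=2)
        fwd = classify.cross_validated_report(fm, ["f0", "noise0", "noise1"], seed=1)
        rev = classify.cross_validated_report(fm, ["noise1", "noise0", "f0"], seed=1)
        assert fwd.accuracy == rev.accuracy

    def test_constant_within_class_feature_is_handled(self, rng):
        """A feature that is constant inside some classes (like BS% for
        awake epochs) must not break the ridge-regularized fit."""
        fm = _gaussian_feature_matrix(rng, [0.0, 4.0, 8.0, 12.0])
        fm.data["flat"] = np.where(fm.labels >= 2, 100.0, 0.0)
        report = classify.cross_validated_report(fm, ["f0", "flat"], seed=0)
        assert report.accuracy > 90.0
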