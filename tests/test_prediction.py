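"""Feature assembly, information-gain selection, and cross-validated prediction."""

import numpy as np
import pandas as pd
import pytest

import unidiag as u
from unidiag.prediction import split_blocks


class TestLabFiveTuple:
    def test_constant_series(self):
        assert u.lab_five_tuple([5, 5, 5]) == (5, 5, 5, 5, 0)

    def test_population_variance(self):
        assert u.lab_five_tuple([1, 2, 3]) == (1, 3, 2, 2, pytest.approx(2 / 3))

    def test_single_value(self):
        assert u.lab_five_tuple([4.5]) == (4.5, 4.5, 4.5, 4.5, 0)

    def test_empty_series_is_nan_sentinel(self):
        assert all(np.isnan(v) for v in u.lab_five_tuple([]))


class TestSymptomExtraction:
    def test_negation_window(self):
        flags = u.extract_symptoms("denies fever, reports cough")
        assert flags["fever"] == 0 and flags["cough"] == 1

    def test_abbreviations(self):
        flags = u.extract_symptoms("SOB on exertion")
        assert flags["shortness_of_breath"] == 1

    def test_empty_text_all_zero(self):
        from unidiag.prediction import SYMPTOM_NAMES

        flags = u.extract_symptoms("")
        assert set(flags) == set(SYMPTOM_NAMES)
        assert not any(flags.values())

    def test_multiword_terms_and_case(self):
        flags = u.extract_symptoms("c/o Night Sweats and loss of appetite")
        assert flags["night_sweating"] == 1 and flags["loss_of_appetite"] == 1

    def test_negation_outside_window_does_not_mask(self):
        text = "no prior admissions for this illness, now with persistent fever"
        assert u.extract_symptoms(text)["fever"] == 1


class TestFuseFeatures:
    @pytest.fixture()
    def blocks(self):
        idx = pd.Index(["p1", "p2", "p3"], name="patient_id")
        de = pd.DataFrame(
            {"age": [40.0, 60.0, 80.0], "admission_type": ["EMERGENCY", "ELECTIVE", "URGENT"]},
            index=idx,
        )
        sy = pd.DataFrame({"fever": [1, 0, 1]}, index=idx)
        le = pd.DataFrame({"wbc_mean": [8.0, 12.0, 10.0]}, index=idx)
        sev = pd.DataFrame({"sofa": [2, 6, 10]}, index=idx)
        return de, sy, le, sev

    def test_one_hot_and_minmax(self, blocks):
        fused = u.fuse_features(*blocks)
        onehot = [c for c in fused.columns if c.startswith("de_admission_type_")]
        assert len(onehot) == 3
        assert fused[onehot].sum(axis=1).eq(1).all()
        numeric = fused["de_age"]
        assert numeric.min() == 0.0 and numeric.max() == 1.0
        assert set(fused["sy_fever"]) <= {0.0, 1.0}

    def test_id_mismatch_rejected(self, blocks):
        de, sy, le, sev = blocks
        with pytest.raises(ValueError, match="p3"):
            u.fuse_features(de, sy.drop(index="p3"), le, sev)

    def test_block_round_trip(self, blocks):
        fused = u.fuse_features(*blocks)
        de, sy, le, sev = split_blocks(fused)
        assert list(sy.columns) == ["sy_fever"]
        assert fused.shape[1] == sum(b.shape[1] for b in (de, sy, le, sev))


class TestInformationGain:
    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        y = rng.integers(0, 2, size=400)
        assert u.information_gain(x, y) < 0.05

    def test_perfect_binary_predictor_is_one_bit(self):
        y = np.array([0, 1] * 50)
        assert u.information_gain(y.copy(), y) == pytest.approx(1.0)

    def test_matches_hand_computed_contingency(self):
        # x:  a a a a b b b b b b ;  y: 3 classes
        x = np.array(list("aaaabbbbbb"))
        y = np.array([0, 0, 1, 2, 1, 1, 1, 2, 2, 2])

        def H(counts):
            p = np.array(counts, dtype=float)
            p = p[p > 0] / p.sum()
            return float(-(p * np.log2(p)).sum())

        expected = H([2, 4, 4]) - (0.4 * H([2, 1, 1]) + 0.6 * H([0, 3, 3]))
        assert u.information_gain(x, y) == pytest.approx(expected)

    def test_constant_labels_give_zero(self):
        assert u.information_gain(np.arange(20), np.zeros(20)) == 0.0


class TestSelectFeatures:
    def test_threshold_is_strict(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 40)
        X = pd.DataFrame(
            {"signal": y.astype(float), "noise": rng.normal(size=80)}
        )
        ig_noise = u.information_gain(X["noise"], y)
        kept, ig = u.select_features(X, y, delta2=float(ig_noise))
        assert "signal" in kept.columns and "noise" not in kept.columns

    def test_informative_features_retained_in_noise_design(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, size=300)
        X = pd.DataFrame(rng.normal(size=(300, 10)), columns=[f"n{i}" for i in range(10)])
        X["inf"] = y + rng.normal(scale=0.1, size=300)
        kept, ig = u.select_features(X, y, delta2=0.25)
        assert list(kept.columns) == ["inf"]

    def test_all_removed_is_rejected(self):
        X = pd.DataFrame({"a": np.zeros(40)})
        y = np.array([0, 1] * 20)
        with pytest.raises(ValueError, match="delta2"):
            u.select_features(X, y, delta2=0.9)


def _separable_data(n=120, k=3, seed=0, informative=2, noise=6):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(k), n // k)
    cols = {}
    for i in range(informative):
        cols[f"inf{i}"] = y * 2.0 + rng.normal(scale=0.3, size=n)
    for i in range(noise):
        cols[f"noise{i}"] = rng.normal(size=n)
    return pd.DataFrame(cols), y


class TestTrainAndEvaluate:
    def test_separable_classes_near_perfect(self):
        X, y = _separable_data()
        report = u.train_and_evaluate(X, y, classifiers=("logistic", "forest"), Z=5)
        assert (report.metrics["acc"] > 0.95).all()
        assert (report.metrics["cv_error"] < 0.05).all()

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(4)
        X, y = _separable_data(n=150)
        y_perm = rng.permutation(y)
        report = u.train_and_evaluate(X, y_perm, classifiers=("forest",), Z=5, delta2=0.0)
        assert abs(report.metrics["acc"].iloc[0] - 1 / 3) < 0.15

    def test_weighted_recall_equals_accuracy(self):
        X, y = _separable_data(n=90, seed=3)
        report = u.train_and_evaluate(X, y, classifiers=("tree",), Z=5)
        assert report.metrics["rec"].iloc[0] == pytest.approx(
            report.metrics["acc"].iloc[0]
        )

    def test_cv_error_is_mean_fold_mismatch(self):
        X, y = _separable_data(n=90, seed=5)
        report = u.train_and_evaluate(X, y, classifiers=("logistic",), Z=5)
        assert report.metrics["cv_error"].iloc[0] == pytest.approx(
            float(np.mean(report.fold_errors["logistic"]))
        )

    def test_metrics_recomputable_from_confusions(self):
        X, y = _separable_data(n=90, seed=6)
        report = u.train_and_evaluate(X, y, classifiers=("forest",), Z=5)
        total = sum(report.confusions["forest"])
        acc = np.trace(total) / total.sum()
        assert acc == pytest.approx(report.metrics["acc"].iloc[0])

    def test_small_class_rejected(self):
        X, y = _separable_data(n=12, k=3)
        with pytest.raises(ValueError, match="smaller Z"):
            u.train_and_evaluate(X, y, classifiers=("tree",), Z=10)

    def test_xgboost_runs_on_small_fixture(self):
        X, y = _separable_data(n=60, seed=7)
        report = u.train_and_evaluate(X, y, classifiers=("xgboost",), Z=5)
        assert report.metrics["acc"].iloc[0] > 0.9

    def test_label_copy_canary_under_permutation_stays_at_chance(self):
        """A feature equal to the unpermuted labels carries no information
        about a permuted target; leakage-free per-fold selection and
        oversampling must therefore leave CV accuracy in the chance band."""
        rng = np.random.default_rng(8)
        n, k = 150, 3
        y_orig = np.repeat(np.arange(k), n // k)
        y = rng.permutation(y_orig)
        X = pd.DataFrame(rng.normal(size=(n, 8)), columns=[f"n{i}" for i in range(8)])
        X["canary"] = y_orig.astype(float)
        report = u.train_and_evaluate(
            X, y, classifiers=("forest",), Z=5, seed=1, delta2=0.0
        )
        assert abs(report.metrics["acc"].iloc[0] - 1 / k) < 0.15


class TestFeatureImportance:
    def test_planted_feature_ranks_first_and_sums_to_one(self):
        X, y = _separable_data(n=120, seed=9, informative=1, noise=7)
        report = u.train_and_evaluate(X, y, classifiers=("forest",), Z=5, delta2=0.0)
        assert report.importances is not None
        assert report.importances.index[0] == "inf0"
        assert report.importances.sum() == pytest.approx(1.0)


class TestClassifierEstimator:
    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = u.UnifyingDiagnosisClassifier(base="tree", delta2=0.01, random_state=3)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()

    def test_fit_predict_roundtrip_with_missing_values(self):
        X, y = _separable_data(n=90, seed=10)
        X.iloc[::7, 0] = np.nan
        model = u.UnifyingDiagnosisClassifier(base="forest", random_state=0)
        model.fit(X, y)
        pred = model.predict(X)
        assert set(pred) <= set(y)
        assert (pred == y).mean() > 0.9
        proba = model.predict_proba(X)
        assert proba.shape == (len(y), 3)
        assert np.allclose(proba.sum(axis=1), 1.0)
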