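"""Cross-validation scheme, classifier wrappers and performance summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import auc_oracle
from patchconn.classify import (
    CLASSIFIER_NAMES,
    CVScheme,
    build_classifier,
    cross_validate,
    make_folds,
    prediction_agreement,
    summarize_performance,
)
from patchconn.core import FeatureMatrix


def make_features(rng, n_per_class, n_features=6, signal=0.0):
    """Gaussian features; `signal` shifts each class mean apart."""
    classes = ("AD", "MCI", "NC")
    rows, labels, sids = [], [], []
    for ci, cls in enumerate(classes):
        n = n_per_class[ci] if hasattr(n_per_class, "__len__") else n_per_class
        x = rng.standard_normal((n, n_features))
        x[:, 0] += signal * ci
        x[:, 1] -= signal * ci
        rows.append(x)
        labels += [cls] * n
        sids += [f"{cls}_{k}" for k in range(n)]
    return FeatureMatrix(
        values=np.vstack(rows), feature_names=[f"f{j}" for j in range(n_features)],
        labels=labels, subject_ids=sids,
    )


class TestMakeFolds:
    def test_balanced_cohort_exact_stratification(self):
        labels = ["AD"] * 30 + ["MCI"] * 30 + ["NC"] * 30
        scheme = CVScheme(n_folds=10, n_repeats=1, base_seed=5)
        folds = make_folds(labels, scheme, repeat=0)
        for f in range(10):
            sub = np.array(labels)[folds == f]
            assert (sub == "AD").sum() == (sub == "MCI").sum() == (sub == "NC").sum() == 3

    def test_unbalanced_cohort_proportions_within_one(self):
        labels = ["AD"] * 92 + ["MCI"] * 214 + ["NC"] * 126
        scheme = CVScheme(n_folds=10, n_repeats=1)
        folds = make_folds(labels, scheme, repeat=0)
        labels = np.array(labels)
        for f in range(10):
            sub = labels[folds == f]
            for cls, total in (("AD", 92), ("MCI", 214), ("NC", 126)):
                assert abs((sub == cls).sum() - total / 10) <= 1

    def test_deterministic_per_repeat_distinct_across(self):
        labels = ["AD"] * 20 + ["MCI"] * 20 + ["NC"] * 20
        scheme = CVScheme(n_folds=10, n_repeats=3, base_seed=1)
        f0a = make_folds(labels, scheme, repeat=0)
        f0b = make_folds(labels, scheme, repeat=0)
        f1 = make_folds(labels, scheme, repeat=1)
        assert np.array_equal(f0a, f0b)
        assert not np.array_equal(f0a, f1)

    def test_small_class_raises(self):
        labels = ["AD"] * 5 + ["MCI"] * 20 + ["NC"] * 20
        with pytest.raises(ValueError, match="fewer members"):
            make_folds(labels, CVScheme(n_folds=10), repeat=0)


class TestBuildClassifier:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_all_families_fit_and_score(self, name, rng):
        X = rng.standard_normal((30, 4))
        y = np.repeat([0, 1, 2], 10)
        X[y == 1, 0] += 3
        X[y == 2, 1] += 3
        model = build_classifier(name, seed=0)
        model.fit(X, y)
        proba = model.predict_proba(X)
        assert proba.shape == (30, 3)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            build_classifier("MLP", seed=0)

    def test_scaled_families_are_pipelines(self):
        for name in ("SVM", "NB", "LR"):
            assert hasattr(build_classifier(name, 0), "steps")
        for name in ("RF", "XGBoost"):
            assert not hasattr(build_classifier(name, 0), "steps")


class TestCrossValidate:
    def test_record_count_and_columns(self, rng):
        fm = make_features(rng, 12, signal=2.0)
        scheme = CVScheme(n_folds=4, n_repeats=2, base_seed=0)
        recs = cross_validate(fm, scheme, classifiers=("RF", "NB"))
        assert len(recs) == 2 * 36 * 2  # repeats x subjects x classifiers
        assert {"score_AD", "score_MCI", "score_NC"} <= set(recs.columns)
        # each subject appears exactly once per repeat per classifier
        counts = recs.groupby(["classifier", "repeat", "subject_id"]).size()
        assert (counts == 1).all()

    def test_separable_problem_high_accuracy(self, rng):
        fm = make_features(rng, 20, signal=6.0)
        scheme = CVScheme(n_folds=4, n_repeats=1, base_seed=3)
        recs = cross_validate(fm, scheme, classifiers=("RF", "NB", "LR"))
        for name in ("RF", "NB", "LR"):
            sub = recs[recs.classifier == name]
            acc = (sub.true_label == sub.predicted_label).mean()
            assert acc > 0.9, name

    def test_chance_level_on_pure_noise(self, rng):
        fm = make_features(rng, 20, signal=0.0)
        scheme = CVScheme(n_folds=4, n_repeats=3, base_seed=11)
        recs = cross_validate(fm, scheme, classifiers=("NB",))
        acc = (recs.true_label == recs.predicted_label).mean()
        # 99.9% binomial band around 1/3 (records are correlated across
        # repeats, so use the per-repeat n for a conservative band)
        half_width = 3.3 * np.sqrt((1 / 3) * (2 / 3) / 60)
        assert abs(acc - 1 / 3) < 2 * half_width

    def test_deterministic(self, rng):
        fm = make_features(rng, 12, signal=1.0)
        scheme = CVScheme(n_folds=3, n_repeats=1, base_seed=9)
        r1 = cross_validate(fm, scheme, classifiers=("RF",))
        r2 = cross_validate(fm, scheme, classifiers=("RF",))
        pd.testing.assert_frame_equal(r1, r2)

    def test_no_test_row_leakage(self, rng):
        """Perturbing some test rows leaves other same-fold predictions alone.

        With 2 folds, fold-0 models are trained on fold-1 rows only; noising
        half of fold 0's rows must not change predictions for the untouched
        fold-0 rows (the model never saw any fold-0 row).
        """
        fm = make_features(rng, 12, signal=1.0)
        scheme = CVScheme(n_folds=2, n_repeats=1, base_seed=4)
        folds = make_folds(fm.labels, scheme, repeat=0)
        fold0 = np.nonzero(folds == 0)[0]
        touched, untouched = fold0[: len(fold0) // 2], fold0[len(fold0) // 2 :]
        values2 = fm.values.copy()
        values2[touched] += rng.standard_normal(values2[touched].shape) * 10
        fm2 = FeatureMatrix(values=values2, feature_names=fm.feature_names,
                            labels=fm.labels, subject_ids=fm.subject_ids)
        r1 = cross_validate(fm, scheme, classifiers=("RF",))
        r2 = cross_validate(fm2, scheme, classifiers=("RF",))
        ids_untouched = set(np.asarray(fm.subject_ids)[untouched])
        score_cols = ["score_AD", "score_MCI", "score_NC"]
        a = r1[(r1.fold == 0) & r1.subject_id.isin(ids_untouched)].sort_values("subject_id")
        b = r2[(r2.fold == 0) & r2.subject_id.isin(ids_untouched)].sort_values("subject_id")
        assert np.allclose(a[score_cols].to_numpy(), b[score_cols].to_numpy())

    def test_unknown_classifier_raises(self, rng):
        fm = make_features(rng, 8)
        with pytest.raises(ValueError, match="unknown classifier"):
            cross_validate(fm, CVScheme(n_folds=2, n_repeats=1), classifiers=("Nope",))


class TestSummarize:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(rows)

    def test_perfect_predictions(self, rng):
        fm = make_features(rng, 12, signal=8.0)
        recs = cross_validate(fm, CVScheme(n_folds=3, n_repeats=2), ("RF",))
        summary = summarize_performance(recs)
        assert summary.mean_accuracy("RF") > 0.95
        assert (summary.auc.auc > 0.95).all()
        conf = summary.confusion["RF"]
        assert list(conf.index) == ["AD", "MCI", "NC"]
        assert conf.to_numpy().sum() == pytest.approx(36)  # subjects per repeat

    def test_auc_matches_mann_whitney_oracle(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(30):
            true = ["AD", "MCI", "NC"][i % 3]
            s = rng.random(3)
            s /= s.sum()
            rows.append(
                {
                    "subject_id": f"s{i}", "repeat": 0, "fold": i % 5,
                    "classifier": "RF", "true_label": true,
                    "predicted_label": "AD",
                    "score_AD": s[0], "score_MCI": s[1], "score_NC": s[2],
                }
            )
        recs = self._records(rows)
        summary = summarize_performance(recs)
        for cls in ("AD", "MCI", "NC"):
            expect = auc_oracle(
                recs[f"score_{cls}"].to_numpy(), (recs.true_label == cls).to_numpy()
            )
            got = summary.auc.loc[summary.auc["class"] == cls, "auc"].iloc[0]
            assert got == pytest.approx(expect, abs=1e-12)

    def test_constant_scores_auc_half(self):
        rows = [
            {
                "subject_id": f"s{i}", "repeat": 0, "fold": 0, "classifier": "RF",
                "true_label": ["AD", "MCI", "NC"][i % 3], "predicted_label": "AD",
                "score_AD": 1 / 3, "score_MCI": 1 / 3, "score_NC": 1 / 3,
            }
            for i in range(12)
        ]
        summary = summarize_performance(self._records(rows))
        assert np.allclose(summary.auc.auc, 0.5)

    def test_empty_records_raise(self):
        with pytest.raises(ValueError, match="no prediction records"):
            summarize_performance(pd.DataFrame())

    def test_accuracy_is_mean_of_fold_accuracies(self, rng):
        fm = make_features(rng, 8, signal=1.0)
        recs = cross_validate(fm, CVScheme(n_folds=4, n_repeats=1), ("NB",))
        summary = summarize_performance(recs)
        manual = np.mean(
            [
                (d.true_label == d.predicted_label).mean()
                for _, d in recs.groupby("fold")
            ]
        )
        assert summary.mean_accuracy("NB") == pytest.approx(manual)


class TestAgreement:
    def test_self_agreement_is_one(self, rng):
        fm = make_features(rng, 8, signal=1.0)
        recs = cross_validate(fm, CVScheme(n_folds=2, n_repeats=1), ("RF",))
        agree = prediction_agreement(recs, recs)
        assert all(v == pytest.approx(1.0) for v in agree.values())

    def test_mismatched_records_raise(self, rng):
        fm = make_features(rng, 8)
        recs = cross_validate(fm, CVScheme(n_folds=2, n_repeats=1), ("RF",))
        with pytest.raises(ValueError, match="different subjects"):
            prediction_agreement(recs, recs.iloc[:-2])

    def test_matches_pearson_oracle(self, rng):
        fm = make_features(rng, 8, signal=1.0)
        recs = cross_validate(fm, CVScheme(n_folds=2, n_repeats=1), ("RF", "NB"))
        a = recs[recs.classifier == "RF"]
        b = recs[recs.classifier == "NB"]
        agree = prediction_agreement(a, b)
        keys = ["subject_id", "repeat", "fold"]
        a = a.sort_values(keys)
        b = b.sort_values(keys)
        for cls in ("AD", "MCI", "NC"):
            r, _ = stats.pearsonr(a[f"score_{cls}"], b[f"score_{cls}"])
            assert agree[cls] == pytest.approx(r, abs=1e-12)
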