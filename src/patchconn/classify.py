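"""Repeated stratified k-fold multi-class classification.

Five model families (RF, SVM, XGBoost, NB, LR) are evaluated inside a
10-fold stratified cross-validation repeated 50 times (defaults).  The
point of running several families is to show the signal lives in the
network features, not in a particular learner, so hyperparameters are
fixed, documented defaults rather than tuned.  Performance is summarised
as per-repeat accuracy, per-class one-vs-rest ROC/AUC and a pooled
confusion matrix; agreement between two classifiers' probability scores is
measured by per-class Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import FeatureMatrix

CLASSIFIER_NAMES = ("RF", "SVM", "XGBoost", "NB", "LR")

#: Classifiers whose features are standardised with train-fold mean/sd.
_SCALED = {"SVM", "NB", "LR"}


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold scheme; folds are seeded per repeat."""

    n_folds: int = 10
    n_repeats: int = 50
    base_seed: int = 0
    stratified: bool = True

    def repeat_seed(self, repeat: int) -> int:
        # distinct, stable stream per repeat, kept below 2**31
        return (self.base_seed * 100_003 + repeat) % (2**31 - 1)


def make_folds(labels, scheme: CVScheme, repeat: int) -> np.ndarray:
    """Test-fold index (0..n_folds-1) for every subject, one repeat.

    Stratified so per-fold class proportions deviate from the cohort's by
    at most one subject per class.  Deterministic in (base_seed, repeat).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < scheme.n_folds]
    if small.size:
        raise ValueError(
            f"classes {small.tolist()} have fewer members than n_folds"
        )
    if scheme.stratified:
        splitter = StratifiedKFold(
            n_splits=scheme.n_folds,
            shuffle=True,
            random_state=scheme.repeat_seed(repeat),
        )
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(
            n_splits=scheme.n_folds,
            shuffle=True,
            random_state=scheme.repeat_seed(repeat),
        )
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(
        splitter.split(np.zeros(len(labels)), labels)
    ):
        assignment[test_idx] = fold
    return assignment


def build_classifier(name: str, seed: int):
    """A fresh estimator with the package's fixed default settings.

    Tree models consume raw features; SVM/LR/NB sit behind a train-fold
    StandardScaler in a Pipeline so no test-fold statistics leak in.
    """
    if name == "RF":
        est = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    elif name == "SVM":
        est = SVC(kernel="rbf", probability=True, random_state=seed)
    elif name == "XGBoost":
        from xgboost import XGBClassifier

        est = XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    elif name == "NB":
        est = GaussianNB()
    elif name == "LR":
        # L2-regularised (the default penalty), C = 1.0
        est = LogisticRegression(C=1.0, max_iter=5000)
    else:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    if name in _SCALED:
        return make_pipeline(StandardScaler(), est)
    return est


def _encode(labels, classes):
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[l] for l in labels])


def cross_validate(
    X: FeatureMatrix,
    scheme: CVScheme,
    classifiers=("RF",),
) -> pd.DataFrame:
    """Fit/test every classifier in every repeat x fold; return all records.

    One row per (repeat, fold, classifier, test subject) with the class
    probability scores, the argmax prediction (ties broken toward the
    lexicographically first class) and the truth.  Models see training rows
    only.
    """
    unknown = set(classifiers) - set(CLASSIFIER_NAMES)
    if unknown:
        raise ValueError(f"unknown classifier names: {sorted(unknown)}")
    classes = X.classes()
    y = _encode(X.labels, classes)
    sids = np.asarray(X.subject_ids)
    records = []
    for repeat in range(scheme.n_repeats):
        folds = make_folds(X.labels, scheme, repeat)
        for fold in range(scheme.n_folds):
            test = folds == fold
            train = ~test
            for name in classifiers:
                model = build_classifier(name, seed=scheme.repeat_seed(repeat))
                model.fit(X.values[train], y[train])
                proba = model.predict_proba(X.values[test])
                # model.classes_ are encoded ints; restore full class order
                order = np.asarray(
                    model.classes_
                    if not hasattr(model, "steps")
                    else model.steps[-1][1].classes_
                )
                full = np.zeros((proba.shape[0], len(classes)))
                full[:, order] = proba
                pred = np.argmax(full, axis=1)  # first max = lexicographic tie-break
                for i, row in enumerate(np.nonzero(test)[0]):
                    rec = {
                        "subject_id": sids[row],
                        "repeat": repeat,
                        "fold": fold,
                        "classifier": name,
                        "true_label": classes[y[row]],
                        "predicted_label": classes[pred[i]],
                    }
                    for k, c in enumerate(classes):
                        rec[f"score_{c}"] = full[i, k]
                    records.append(rec)
    return pd.DataFrame.from_records(records)


def _score_columns(records: pd.DataFrame) -> list[str]:
    return sorted(c for c in records.columns if c.startswith("score_"))


@dataclass
class PerformanceSummary:
    """Per-repeat accuracy/AUC distributions and the pooled confusion matrix."""

    accuracy: pd.DataFrame  # columns: classifier, repeat, accuracy
    auc: pd.DataFrame  # columns: classifier, repeat, class, auc
    confusion: dict[str, pd.DataFrame]  # classifier -> pooled matrix (mean/repeat)
    roc_curves: pd.DataFrame  # pooled per-class ROC points per classifier

    def mean_accuracy(self, classifier: str) -> float:
        a = self.accuracy
        return float(a.loc[a.classifier == classifier, "accuracy"].mean())


def summarize_performance(records: pd.DataFrame) -> PerformanceSummary:
    """Accuracy per repeat, one-vs-rest AUC per class per repeat, confusion.

    Accuracy for a repeat is the mean over folds of the fold accuracy; AUC
    pools a repeat's test predictions and scores each class one-vs-rest;
    the confusion matrix is summed within a repeat and averaged across
    repeats (true class in rows, predicted in columns).
    """
    if records.empty:
        raise ValueError("no prediction records")
    classes = sorted(records["true_label"].unique())
    acc_rows, auc_rows, conf = [], [], {}
    roc_rows = []
    for name, recs in records.groupby("classifier"):
        mats = []
        for repeat, rep in recs.groupby("repeat"):
            fold_acc = rep.groupby("fold").apply(
                lambda d: float((d.true_label == d.predicted_label).mean()),
                include_groups=False,
            )
            acc_rows.append(
                {"classifier": name, "repeat": repeat, "accuracy": float(fold_acc.mean())}
            )
            for c in classes:
                truth = (rep.true_label == c).astype(int)
                if truth.nunique() < 2:
                    continue
                auc_rows.append(
                    {
                        "classifier": name,
                        "repeat": repeat,
                        "class": c,
                        "auc": float(roc_auc_score(truth, rep[f"score_{c}"])),
                    }
                )
            mats.append(
                confusion_matrix(rep.true_label, rep.predicted_label, labels=classes)
            )
        conf[name] = pd.DataFrame(
            np.mean(mats, axis=0), index=classes, columns=classes
        )
        for c in classes:
            truth = (recs.true_label == c).astype(int)
            if truth.nunique() < 2:
                continue
            fpr, tpr, thr = roc_curve(truth, recs[f"score_{c}"])
            roc_rows.append(
                pd.DataFrame(
                    {"classifier": name, "class": c, "fpr": fpr, "tpr": tpr}
                )
            )
    return PerformanceSummary(
        accuracy=pd.DataFrame(acc_rows),
        auc=pd.DataFrame(auc_rows),
        confusion=conf,
        roc_curves=pd.concat(roc_rows, ignore_index=True)
        if roc_rows
        else pd.DataFrame(columns=["classifier", "class", "fpr", "tpr"]),
    )


def prediction_agreement(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> dict[str, float]:
    """Per-class Pearson correlation of two classifiers' probability scores.

    Records must cover the same (subject, repeat, fold) test predictions.
    """
    keys = ["subject_id", "repeat", "fold"]
    a = records_a.sort_values(keys).reset_index(drop=True)
    b = records_b.sort_values(keys).reset_index(drop=True)
    if len(a) != len(b) or not a[keys].equals(b[keys]):
        raise ValueError("record sets cover different subjects/folds/repeats")
    out = {}
    for col in _score_columns(a):
        cls = col.removeprefix("score_")
        out[cls] = float(np.corrcoef(a[col], b[col])[0, 1])
    return out
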