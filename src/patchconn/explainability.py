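"""Shapley-value explanations of the reduced per-fold models.

Every test subject of every cross-validation round gets an additive
attribution: a baseline E[f(x)] (mean model output over the training
background) plus one term per selected feature, summing exactly to the
subject's own score f(x).  For the multiclass model f is the probability
of the subject's true class (configurable to the predicted class); the
three one-vs-rest models are explained on the positive-class probability.
Mean absolute attributions aggregate into global and class-specific
importance rankings; class rankings use only correctly classified subjects
(judged by the one-vs-rest model itself) and rankings are compared by
Spearman correlation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from ._forest import ForestEvaluator
from . import shapley as _shapley

logger = logging.getLogger(__name__)

MULTICLASS = "multiclass"


def one_vs_rest_scope(target_class: str) -> str:
    return f"one_vs_rest:{target_class}"


@dataclass
class ShapExplanation:
    """Additive decomposition of one subject's prediction in one fold."""

    subject_id: str
    repeat: int
    fold: int
    model_scope: str
    baseline: float
    phi: dict[str, float]
    prediction: float
    true_label: str = ""
    predicted_correctly: bool = True
    feature_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gap = abs(self.baseline + sum(self.phi.values()) - self.prediction)
        if gap > 1e-6:
            raise ValueError(
                f"additivity violated by {gap:.2e} for subject {self.subject_id}"
            )


@dataclass
class ExplainConfig:
    """Estimator and restriction settings for the explanation stage."""

    background_size: int = 16
    n_permutations: int = 128
    explain_target: str = "true_class"  # or "predicted_class"
    base_seed: int = 0


@dataclass
class ImportanceRanking:
    """Features ranked by mean |phi| (descending; name breaks ties)."""

    scope: str
    scores: dict[str, float]
    ranked_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ranked_features = sorted(
            self.scores, key=lambda f: (-self.scores[f], f)
        )

    def top(self, k: int) -> list[str]:
        return self.ranked_features[:k]


def shapley_values(
    model,
    x: np.ndarray,
    background: np.ndarray,
    feature_names: list[str],
    class_index: int = 0,
    subject_id: str = "",
    repeat: int = 0,
    fold: int = 0,
    model_scope: str = MULTICLASS,
    true_label: str = "",
    predicted_correctly: bool = True,
    n_permutations: int = 128,
    seed: int = 0,
) -> ShapExplanation:
    """Explain one subject's score on one fitted model.

    Exact coalition enumeration when the model has few enough features
    (the usual case after selection), a seeded sampling estimator
    otherwise.  ``class_index`` picks which probability column f reports.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != len(feature_names):
        raise ValueError("x length does not match feature_names")
    if getattr(model, "n_features_in_", len(feature_names)) != len(feature_names):
        raise ValueError("model and x disagree on the number of features")
    predict = _model_score_fn(model, class_index)
    phi, baseline = _shapley.shapley_values(
        predict,
        x[None, :],
        background,
        n_permutations=n_permutations,
        seed=seed,
    )
    return ShapExplanation(
        subject_id=subject_id,
        repeat=repeat,
        fold=fold,
        model_scope=model_scope,
        baseline=baseline,
        phi=dict(zip(feature_names, phi[0])),
        prediction=float(predict(x[None, :])[0]),
        true_label=true_label,
        predicted_correctly=predicted_correctly,
        feature_values=dict(zip(feature_names, x)),
    )


def _model_score_fn(model, class_index: int):
    if isinstance(model, RandomForestClassifier):
        return ForestEvaluator(model).class_score(class_index)
    return lambda A: np.asarray(model.predict_proba(A))[:, class_index]


def train_one_vs_rest(
    X_train: np.ndarray,
    y_train,
    target_class: str,
    seed: int = 0,
    n_estimators: int = 100,
) -> RandomForestClassifier:
    """Binary forest separating ``target_class`` from the rest."""
    y = (np.asarray(y_train) == target_class).astype(int)
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(X_train, y)
    return model


def explain_fold(
    reduced_model: RandomForestClassifier,
    X_train_sel: np.ndarray,
    y_train,
    X_test_sel: np.ndarray,
    test_subject_ids,
    test_true_labels,
    feature_names_sel: list[str],
    repeat: int,
    fold: int,
    config: ExplainConfig,
    classes: list[str] | None = None,
    ovr_models: dict[str, RandomForestClassifier] | None = None,
) -> list[ShapExplanation]:
    """All explanations (multiclass + one-vs-rest) for one fold's test set.

    The background is a seeded subsample of the training rows; all test
    subjects of the fold share it, which lets coalition values be evaluated
    in one batched pass per model.
    """
    y_train = np.asarray(y_train)
    test_true_labels = np.asarray(test_true_labels)
    if classes is None:
        classes = sorted(set(y_train))
    rng = np.random.default_rng(
        np.random.SeedSequence((config.base_seed, repeat, fold))
    )
    n_train = X_train_sel.shape[0]
    take = min(config.background_size, n_train)
    background = X_train_sel[rng.choice(n_train, size=take, replace=False)]
    seed = int(rng.integers(2**31 - 1))

    out: list[ShapExplanation] = []
    class_index = {c: i for i, c in enumerate(classes)}

    # multiclass scope: one batch per target class present in the test fold
    ev = ForestEvaluator(reduced_model)
    proba = ev.proba(X_test_sel)
    pred_label = np.array([classes[i] for i in np.argmax(proba, axis=1)])
    if config.explain_target == "true_class":
        targets = test_true_labels
    elif config.explain_target == "predicted_class":
        targets = pred_label
    else:
        raise ValueError(f"unknown explain_target {config.explain_target!r}")
    for cls in classes:
        rows = np.nonzero(targets == cls)[0]
        if rows.size == 0:
            continue
        phi, baseline = _shapley.shapley_values(
            ev.class_score(class_index[cls]),
            X_test_sel[rows],
            background,
            n_permutations=config.n_permutations,
            seed=seed,
        )
        for k, r in enumerate(rows):
            out.append(
                ShapExplanation(
                    subject_id=str(test_subject_ids[r]),
                    repeat=repeat,
                    fold=fold,
                    model_scope=MULTICLASS,
                    baseline=baseline,
                    phi=dict(zip(feature_names_sel, phi[k])),
                    prediction=float(proba[r, class_index[cls]]),
                    true_label=str(test_true_labels[r]),
                    predicted_correctly=bool(pred_label[r] == test_true_labels[r]),
                    feature_values=dict(zip(feature_names_sel, X_test_sel[r])),
                )
            )

    # one-vs-rest scopes
    if ovr_models is None:
        ovr_models = {
            c: train_one_vs_rest(
                X_train_sel, y_train, c, seed=(seed + i) % (2**31 - 1)
            )
            for i, c in enumerate(classes)
        }
    for cls, model in ovr_models.items():
        evb = ForestEvaluator(model)
        score = evb.class_score(1)  # probability of "is target class"
        f_test = score(X_test_sel)
        member = test_true_labels == cls
        correct = (f_test >= 0.5) == member
        phi, baseline = _shapley.shapley_values(
            score,
            X_test_sel,
            background,
            n_permutations=config.n_permutations,
            seed=seed,
        )
        for r in range(X_test_sel.shape[0]):
            out.append(
                ShapExplanation(
                    subject_id=str(test_subject_ids[r]),
                    repeat=repeat,
                    fold=fold,
                    model_scope=one_vs_rest_scope(cls),
                    baseline=baseline,
                    phi=dict(zip(feature_names_sel, phi[r])),
                    prediction=float(f_test[r]),
                    true_label=str(test_true_labels[r]),
                    predicted_correctly=bool(correct[r]),
                    feature_values=dict(zip(feature_names_sel, X_test_sel[r])),
                )
            )
    return out


def global_ranking(explanations: list[ShapExplanation]) -> ImportanceRanking:
    """Mean |phi| over all multiclass explanations, ranked descending.

    A feature absent from a fold's selection contributes no term to its
    mean (rather than zeros), so fold-varying selections do not dilute
    scores.
    """
    expls = [e for e in explanations if e.model_scope == MULTICLASS]
    if not expls:
        raise ValueError("no multiclass explanations given")
    return _ranking_from(expls, MULTICLASS)


def _ranking_from(expls: list[ShapExplanation], scope: str) -> ImportanceRanking:
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for e in expls:
        for f, p in e.phi.items():
            sums[f] = sums.get(f, 0.0) + abs(p)
            counts[f] = counts.get(f, 0) + 1
    scores = {f: sums[f] / counts[f] for f in sums}
    return ImportanceRanking(scope=scope, scores=scores)


def class_ranking(
    explanations: list[ShapExplanation],
    target_class: str,
    restrict_by: str = "ovr",
) -> ImportanceRanking:
    """Ranking from one-vs-rest explanations of correctly classified subjects.

    ``restrict_by='ovr'`` judges correctness by the one-vs-rest model
    itself (default); ``'multiclass'`` uses the multiclass prediction
    recorded on the matching multiclass explanations.
    """
    scope = one_vs_rest_scope(target_class)
    expls = [e for e in explanations if e.model_scope == scope]
    if restrict_by == "ovr":
        kept = [e for e in expls if e.predicted_correctly]
    elif restrict_by == "multiclass":
        ok = {
            (e.subject_id, e.repeat, e.fold)
            for e in explanations
            if e.model_scope == MULTICLASS and e.predicted_correctly
        }
        kept = [e for e in expls if (e.subject_id, e.repeat, e.fold) in ok]
    else:
        raise ValueError(f"unknown restrict_by {restrict_by!r}")
    if not kept:
        warnings.warn(
            f"no correctly classified subjects for class {target_class}; "
            "empty ranking",
            stacklevel=2,
        )
        return ImportanceRanking(scope=scope, scores={})
    return _ranking_from(kept, scope)


def _exact_spearman_pvalue(r1: np.ndarray, r2: np.ndarray, rho: float) -> float:
    """Two-sided permutation p-value enumerating all n! orderings."""
    n = len(r1)
    c1 = r1 - r1.mean()
    denom = np.sqrt((c1**2).sum())
    hits = 0
    total = 0
    chunk = []
    target = abs(rho) - 1e-12

    def flush(chunk):
        nonlocal hits, total
        arr = np.asarray(chunk, dtype=float)
        c2 = arr - arr.mean(axis=1, keepdims=True)
        d2 = np.sqrt((c2**2).sum(axis=1))
        rhos = (c2 @ c1) / (d2 * denom)
        hits += int((np.abs(rhos) >= target).sum())
        total += len(arr)

    for perm in itertools.permutations(r2):
        chunk.append(perm)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return hits / total


def compare_rankings(
    r1: ImportanceRanking,
    r2: ImportanceRanking,
    exact_max: int = 10,
) -> tuple[float, float]:
    """Spearman rho between two rankings over their common features.

    Ranks come from the scores (average ranks on ties).  The p-value is
    the usual two-sided t approximation, replaced by an exact permutation
    enumeration when the intersection has at most ``exact_max`` features.
    """
    common = sorted(set(r1.scores) & set(r2.scores))
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 common features to compare rankings (got {len(common)})"
        )
    s1 = np.array([r1.scores[f] for f in common])
    s2 = np.array([r2.scores[f] for f in common])
    rank1 = stats.rankdata(-s1)
    rank2 = stats.rankdata(-s2)
    rho = float(stats.pearsonr(rank1, rank2)[0])
    if len(common) <= exact_max:
        p = _exact_spearman_pvalue(rank1, rank2, rho)
    else:
        p = float(stats.spearmanr(s1, s2).pvalue)
    return rho, p


def compare_all_rankings(
    rankings: dict[str, ImportanceRanking], exact_max: int = 10
) -> pd.DataFrame:
    """Pairwise Spearman comparison table (pair, rho, p)."""
    rows = []
    names = list(rankings)
    for a, b in itertools.combinations(names, 2):
        try:
            rho, p = compare_rankings(rankings[a], rankings[b], exact_max=exact_max)
        except ValueError:
            rho, p = np.nan, np.nan
        rows.append({"ranking_a": a, "ranking_b": b, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


def waterfall_data(expl: ShapExplanation, top_k: int) -> pd.DataFrame:
    """Per-subject additive contribution table behind a waterfall plot.

    Top-k features by |phi| with their signed contributions, plus a
    ``(rest)`` row pooling the remainder; baseline + column sum equals the
    prediction exactly.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    items = sorted(expl.phi.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    head = items[:top_k]
    rest = sum(p for _, p in items[top_k:])
    rows = [
        {"feature": f, "phi": p, "feature_value": expl.feature_values.get(f)}
        for f, p in head
    ]
    rows.append({"feature": "(rest)", "phi": rest, "feature_value": None})
    df = pd.DataFrame(rows)
    df.attrs["baseline"] = expl.baseline
    df.attrs["prediction"] = expl.prediction
    return df


def beeswarm_data(explanations: list[ShapExplanation]) -> pd.DataFrame:
    """Long-format table (scope, subject, feature, phi, feature value)."""
    rows = []
    for e in explanations:
        for f, p in e.phi.items():
            rows.append(
                {
                    "model_scope": e.model_scope,
                    "subject_id": e.subject_id,
                    "repeat": e.repeat,
                    "fold": e.fold,
                    "feature": f,
                    "phi": p,
                    "feature_value": e.feature_values.get(f),
                }
            )
    return pd.DataFrame(rows)


def explanations_to_frame(explanations: list[ShapExplanation]) -> pd.DataFrame:
    """Long-format CSV-ready table of all attributions."""
    rows = []
    for e in explanations:
        for f, p in e.phi.items():
            rows.append(
                {
                    "subject_id": e.subject_id,
                    "repeat": e.repeat,
                    "fold": e.fold,
                    "model_scope": e.model_scope,
                    "feature": f,
                    "phi": p,
                    "baseline": e.baseline,
                    "prediction": e.prediction,
                    "true_label": e.true_label,
                    "predicted_correctly": e.predicted_correctly,
                }
            )
    return pd.DataFrame(rows)
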