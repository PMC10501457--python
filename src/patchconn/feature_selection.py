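"""Per-fold importance screening and reduced-model retraining.

Inside every cross-validation fold a random forest is fitted on the
training rows and each feature's Mean Decrease Accuracy (MDA) is measured:
the drop in out-of-bag accuracy when that feature's column is permuted,
averaged over B independent permutations.  Two filters follow:

1. keep features whose MDA exceeds the 95th percentile of the fold's MDA
   distribution (strictly; cutoff ties are dropped for determinism);
2. keep those whose accuracy dropped in significantly more than half of the
   B permutation rounds, by an exact one-sided binomial test against
   Bin(B, 1/2) at the 5% level.

The paper-style construction of the binomial test (trials = permutation
rounds, success = any positive accuracy drop, null p = 1/2) is one
plausible operationalisation and is isolated in :func:`binomial_filter` so
alternatives can be swapped.  A fresh, smaller forest is retrained on the
selected columns for the explanation stage.  Everything is fold-local: no
test row influences the selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the two-stage screen.

    B permutations per feature; q-th percentile MDA screen; alpha level of
    the one-sided binomial filter; size of the forests used for importance
    and for the reduced model.
    """

    n_permutations: int = 30
    percentile: float = 95.0
    alpha: float = 0.05
    n_estimators: int = 200
    reduced_estimators: int = 100
    fallback_top: int = 10
    base_seed: int = 0


@dataclass
class FoldSelection:
    """Outcome of the screen in one (repeat, fold)."""

    repeat: int
    fold: int
    table: pd.DataFrame  # feature, mda, drop_count, p_value, selected
    selected_features: list[str]
    reduced_model: RandomForestClassifier | None = None
    used_fallback: bool = False

    @property
    def mda_scores(self) -> dict[str, float]:
        return dict(zip(self.table.feature, self.table.mda))

    @property
    def binomial_pvalues(self) -> dict[str, float]:
        return dict(zip(self.table.feature, self.table.p_value))


class _OOBForest:
    """Cached leaf tables for fast out-of-bag accuracy under permutations.

    The forest's aggregated out-of-bag class votes are precomputed once;
    permuting one feature column only reroutes rows in the trees that
    split on that feature, so those trees' leaf contributions are swapped
    out with direct C-level ``tree_.apply`` calls and numpy gathers.  This
    makes B permutation rounds per feature cost far less than B full
    ``predict`` passes over the forest.
    """

    def __init__(self, forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray):
        self.forest = forest
        self.X32 = np.ascontiguousarray(X, dtype=np.float32)
        self.y = np.asarray(y)
        n = self.X32.shape[0]
        self.n = n
        n_trees = len(forest.estimators_)
        oob = np.ones((n_trees, n), dtype=bool)
        for t, sampled in enumerate(forest.estimators_samples_):
            oob[t, sampled] = False
        self.oob = oob
        self.covered = oob.any(axis=0)
        # per-leaf class-probability tables and which features each tree uses
        self.values = []
        self.tree_features: list[np.ndarray] = []
        base_agg = np.zeros((n, forest.n_classes_))
        self.base_contrib = []
        for t, est in enumerate(forest.estimators_):
            v = est.tree_.value[:, 0, :]
            v = v / np.clip(v.sum(axis=1, keepdims=True), 1e-12, None)
            self.values.append(v)
            feats = est.tree_.feature
            self.tree_features.append(np.unique(feats[feats >= 0]))
            contrib = v[est.tree_.apply(self.X32)] * oob[t][:, None]
            self.base_contrib.append(contrib)
            base_agg += contrib
        self.base_agg = base_agg

    def base_accuracy(self) -> float:
        pred = np.argmax(self.base_agg, axis=1)
        return float((pred == self.y)[self.covered].mean())

    def permuted_accuracy(self, j: int, perms: np.ndarray) -> np.ndarray:
        """OOB accuracy after permuting column ``j`` by each row of ``perms``.

        ``perms`` has shape (B, n): B row permutations.  Only trees that
        split on feature ``j`` are re-applied.
        """
        n, B = self.n, perms.shape[0]
        affected = [
            t for t, used in enumerate(self.tree_features) if j in used
        ]
        if not affected:
            base = self.base_accuracy()
            return np.full(B, base)
        stacked = np.tile(self.X32, (B, 1))
        for b in range(B):
            stacked[b * n : (b + 1) * n, j] = self.X32[perms[b], j]
        agg = np.tile(self.base_agg, (B, 1))
        oob_tiled_cache: dict[int, np.ndarray] = {}
        for t in affected:
            leaves = self.forest.estimators_[t].tree_.apply(stacked)
            contrib = self.values[t][leaves]
            mask = np.tile(self.oob[t], B)
            contrib[~mask] = 0.0
            agg += contrib - np.tile(self.base_contrib[t], (B, 1))
        pred = np.argmax(agg, axis=1).reshape(B, n)
        correct = pred == self.y[None, :]
        return correct[:, self.covered].mean(axis=1)


def mda_importance(
    model: RandomForestClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    feature_names: list[str],
    B: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance on the forest's out-of-bag predictions.

    For each feature, B seeded within-column permutations are applied and
    the OOB accuracy drop recorded; the MDA score is the mean drop and
    ``drop_count`` the number of rounds with a strictly positive drop.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    n, d = X_train.shape
    if len(feature_names) != d:
        raise ValueError("feature_names length must match column count")
    helper = _OOBForest(model, X_train, y_train)
    base = helper.base_accuracy()
    rows = []
    for j in range(d):
        rng = np.random.default_rng(np.random.SeedSequence((seed, j)))
        perms = np.stack([rng.permutation(n) for _ in range(B)])
        acc = helper.permuted_accuracy(j, perms)
        drops = base - acc
        rows.append(
            {
                "feature": feature_names[j],
                "mda": float(drops.mean()),
                "drop_count": int((drops > 0).sum()),
                "B": B,
            }
        )
    return pd.DataFrame(rows)


def percentile_screen(
    mda_scores: pd.DataFrame | dict, q: float = 95.0
) -> list[str]:
    """Features whose MDA lies strictly above the q-th percentile.

    Uses the linear-interpolation empirical percentile; features tied with
    the cutoff are excluded, so an all-equal score vector selects nothing.
    """
    if isinstance(mda_scores, dict):
        items = list(mda_scores.items())
    else:
        items = list(zip(mda_scores.feature, mda_scores.mda))
    if len(items) < 20:
        logger.warning(
            "percentile screen over only %d features is close to vacuous",
            len(items),
        )
    scores = np.array([s for _, s in items], dtype=float)
    cutoff = np.percentile(scores, q)
    return [f for f, s in items if s > cutoff]


def binomial_filter(
    drop_counts: dict[str, tuple[int, int]], alpha: float = 0.05
) -> tuple[list[str], dict[str, float]]:
    """Exact one-sided binomial test of "accuracy dropped in k of B rounds".

    Keeps a feature iff P[K >= k | K ~ Bin(B, 1/2)] < alpha.  Returns the
    kept features and all p-values.
    """
    kept, pvals = [], {}
    for feat, (k, B) in drop_counts.items():
        if B < 5:
            raise ValueError("binomial filter needs B >= 5")
        if k > B or k < 0:
            raise ValueError(f"drop count {k} outside 0..{B}")
        p = float(stats.binom.sf(k - 1, B, 0.5))
        pvals[feat] = p
        if p < alpha:
            kept.append(feat)
    return kept, pvals


def select_and_retrain(
    X_train: np.ndarray,
    y_train: np.ndarray,
    feature_names: list[str],
    config: SelectionConfig,
    repeat: int = 0,
    fold: int = 0,
    importance_model: RandomForestClassifier | None = None,
) -> FoldSelection:
    """MDA screen -> percentile filter -> binomial filter -> retrain.

    Runs entirely on training rows.  If the two-stage filter empties the
    selection, the top ``fallback_top`` features by MDA are used instead
    (with a warning), so downstream explanation always has a model.
    """
    seed = (config.base_seed * 7_919 + repeat * 97 + fold) % (2**31 - 1)
    if importance_model is None:
        importance_model = RandomForestClassifier(
            n_estimators=config.n_estimators, random_state=seed, n_jobs=1
        )
        importance_model.fit(X_train, y_train)
    table = mda_importance(
        importance_model,
        X_train,
        y_train,
        feature_names,
        B=config.n_permutations,
        seed=seed,
    )
    screened = set(percentile_screen(table, config.percentile))
    counts = {
        r.feature: (r.drop_count, r.B)
        for r in table.itertuples()
        if r.feature in screened
    }
    kept, pvals = binomial_filter(counts, config.alpha)
    table["p_value"] = [
        pvals.get(f, float(stats.binom.sf(k - 1, b, 0.5)))
        for f, k, b in zip(table.feature, table.drop_count, table.B)
    ]
    used_fallback = False
    if not kept:
        order = table.sort_values(["mda", "feature"], ascending=[False, True])
        kept = order.feature.head(config.fallback_top).tolist()
        used_fallback = True
        logger.warning(
            "repeat %d fold %d: empty selection, falling back to top-%d MDA",
            repeat,
            fold,
            config.fallback_top,
        )
    # keep the original (metric-major) column order for the reduced model
    selected = [f for f in feature_names if f in set(kept)]
    table["selected"] = table.feature.isin(selected)
    cols = [feature_names.index(f) for f in selected]
    reduced = RandomForestClassifier(
        n_estimators=config.reduced_estimators, random_state=seed, n_jobs=1
    )
    reduced.fit(X_train[:, cols], y_train)
    return FoldSelection(
        repeat=repeat,
        fold=fold,
        table=table,
        selected_features=selected,
        reduced_model=reduced,
        used_fallback=used_fallback,
    )
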