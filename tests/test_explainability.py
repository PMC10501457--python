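"""Explanations, importance rankings and their comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from patchconn.explainability import (
    ExplainConfig,
    ImportanceRanking,
    MULTICLASS,
    ShapExplanation,
    beeswarm_data,
    class_ranking,
    compare_all_rankings,
    compare_rankings,
    explain_fold,
    explanations_to_frame,
    global_ranking,
    one_vs_rest_scope,
    shapley_values,
    train_one_vs_rest,
    waterfall_data,
)


def make_expl(phi, scope=MULTICLASS, baseline=0.4, subject_id="s0",
              correct=True, true_label="AD", repeat=0, fold=0):
    return ShapExplanation(
        subject_id=subject_id, repeat=repeat, fold=fold, model_scope=scope,
        baseline=baseline, phi=dict(phi),
        prediction=baseline + sum(phi.values()),
        true_label=true_label, predicted_correctly=correct,
        feature_values={f: 0.0 for f in phi},
    )


def fit_forest(rng, n=90, d=5, gap=3.0, classes=("AD", "MCI", "NC")):
    y = np.repeat(classes, n // len(classes))
    X = rng.standard_normal((n, d))
    for i, c in enumerate(classes):
        X[y == c, i % d] += gap * (i + 1)
    model = RandomForestClassifier(n_estimators=50, random_state=0, n_jobs=1)
    model.fit(X, y)
    return model, X, y


class TestShapExplanation:
    def test_additivity_enforced(self):
        with pytest.raises(ValueError, match="additivity"):
            ShapExplanation(
                subject_id="s", repeat=0, fold=0, model_scope=MULTICLASS,
                baseline=0.5, phi={"a": 0.1}, prediction=0.9,
            )


class TestShapleyValuesOnModels:
    def test_forest_explanation_is_additive(self, rng):
        model, X, y = fit_forest(rng)
        names = [f"f{j}" for j in range(X.shape[1])]
        expl = shapley_values(
            model, X[0], X[10:30], names, class_index=0, subject_id="s0"
        )
        assert expl.prediction == pytest.approx(
            model.predict_proba(X[0:1])[0, 0], abs=1e-9
        )
        assert set(expl.phi) == set(names)

    def test_matches_naive_predict_proba_route(self, rng):
        """ForestEvaluator fast path equals sklearn's predict_proba."""
        model, X, y = fit_forest(rng)
        names = [f"f{j}" for j in range(X.shape[1])]

        class Wrapper:  # force the generic predict_proba code path
            n_features_in_ = X.shape[1]

            def predict_proba(self, A):
                return model.predict_proba(A)

        fast = shapley_values(model, X[3], X[20:36], names, class_index=1)
        slow = shapley_values(Wrapper(), X[3], X[20:36], names, class_index=1)
        for f in names:
            assert fast.phi[f] == pytest.approx(slow.phi[f], abs=1e-9)

    def test_length_mismatch_raises(self, rng):
        model, X, y = fit_forest(rng)
        with pytest.raises(ValueError, match="feature_names"):
            shapley_values(model, X[0], X[1:5], ["only", "two"])


class TestExplainFold:
    def test_scopes_counts_and_additivity(self, rng):
        model, X, y = fit_forest(rng, n=60, d=4)
        names = [f"f{j}" for j in range(4)]
        test_idx = np.arange(0, 60, 10)
        train_idx = np.setdiff1d(np.arange(60), test_idx)
        expls = explain_fold(
            model, X[train_idx], y[train_idx], X[test_idx],
            [f"s{i}" for i in test_idx], y[test_idx], names,
            repeat=0, fold=0, config=ExplainConfig(background_size=16),
        )
        scopes = {e.model_scope for e in expls}
        assert scopes == {MULTICLASS} | {one_vs_rest_scope(c)
                                         for c in ("AD", "MCI", "NC")}
        # every test subject gets 1 multiclass + 3 one-vs-rest explanations
        assert len(expls) == 4 * len(test_idx)

    def test_true_vs_predicted_target(self, rng):
        model, X, y = fit_forest(rng, n=60, d=4, gap=5.0)
        names = [f"f{j}" for j in range(4)]
        test_idx = np.arange(0, 60, 10)
        train_idx = np.setdiff1d(np.arange(60), test_idx)
        kw = dict(
            X_train_sel=X[train_idx], y_train=y[train_idx],
            X_test_sel=X[test_idx],
            test_subject_ids=[f"s{i}" for i in test_idx],
            test_true_labels=y[test_idx], feature_names_sel=names,
            repeat=0, fold=0,
        )
        e_true = explain_fold(model, config=ExplainConfig(
            explain_target="true_class"), **kw)
        e_pred = explain_fold(model, config=ExplainConfig(
            explain_target="predicted_class"), **kw)
        # on a well-separated problem both targets coincide
        mt = {e.subject_id: e.prediction for e in e_true
              if e.model_scope == MULTICLASS}
        mp = {e.subject_id: e.prediction for e in e_pred
              if e.model_scope == MULTICLASS}
        assert mt == mp
        with pytest.raises(ValueError, match="explain_target"):
            explain_fold(model, config=ExplainConfig(explain_target="nope"), **kw)

    def test_deterministic(self, rng):
        model, X, y = fit_forest(rng, n=60, d=4)
        names = [f"f{j}" for j in range(4)]
        test_idx = np.arange(0, 60, 15)
        train_idx = np.setdiff1d(np.arange(60), test_idx)
        args = (model, X[train_idx], y[train_idx], X[test_idx],
                [f"s{i}" for i in test_idx], y[test_idx], names, 2, 3,
                ExplainConfig(base_seed=7))
        e1 = explain_fold(*args)
        e2 = explain_fold(*args)
        assert explanations_to_frame(e1).equals(explanations_to_frame(e2))


class TestTrainOneVsRest:
    def test_binary_and_seeded(self, rng):
        _, X, y = fit_forest(rng)
        model = train_one_vs_rest(X, y, "AD", seed=0)
        assert list(model.classes_) == [0, 1]
        proba = model.predict_proba(X)
        assert (proba[y == "AD", 1] > 0.5).mean() > 0.9


class TestRankings:
    def test_global_ranking_sorts_by_mean_abs_phi(self):
        expls = [
            make_expl({"a": 0.3, "b": -0.1}, baseline=0.2, subject_id="s0"),
            make_expl({"a": -0.3, "b": 0.4}, baseline=0.2, subject_id="s1"),
        ]
        r = global_ranking(expls)
        assert r.scores["a"] == pytest.approx(0.3)
        assert r.scores["b"] == pytest.approx(0.25)
        assert r.ranked_features == ["a", "b"]

    def test_missing_features_do_not_dilute(self):
        expls = [
            make_expl({"a": 0.2}, subject_id="s0"),
            make_expl({"a": 0.2, "b": 0.6}, subject_id="s1"),
        ]
        r = global_ranking(expls)
        assert r.scores["b"] == pytest.approx(0.6)  # mean over 1 expl, not 2

    def test_global_requires_multiclass(self):
        with pytest.raises(ValueError, match="multiclass"):
            global_ranking([make_expl({"a": 0.1}, scope=one_vs_rest_scope("AD"))])

    def test_class_ranking_restricts_to_correct(self):
        scope = one_vs_rest_scope("AD")
        expls = [
            make_expl({"a": 1.0}, scope=scope, correct=True, subject_id="s0"),
            make_expl({"a": 0.0}, scope=scope, correct=False, subject_id="s1"),
        ]
        r = class_ranking(expls, "AD")
        assert r.scores["a"] == pytest.approx(1.0)

    def test_class_ranking_multiclass_restriction(self):
        scope = one_vs_rest_scope("AD")
        expls = [
            make_expl({"a": 1.0}, scope=scope, correct=True, subject_id="s0"),
            make_expl({"a": 0.5}, scope=MULTICLASS, correct=False, subject_id="s0"),
        ]
        with pytest.warns(UserWarning, match="empty ranking"):
            r = class_ranking(expls, "AD", restrict_by="multiclass")
        assert r.scores == {}  # multiclass said wrong -> excluded

    def test_all_wrong_warns_empty(self):
        scope = one_vs_rest_scope("MCI")
        expls = [make_expl({"a": 1.0}, scope=scope, correct=False)]
        with pytest.warns(UserWarning, match="empty ranking"):
            r = class_ranking(expls, "MCI")
        assert r.scores == {} and r.ranked_features == []

    def test_rank_tie_broken_by_name(self):
        r = ImportanceRanking(scope="x", scores={"b": 0.5, "a": 0.5, "c": 0.9})
        assert r.ranked_features == ["c", "a", "b"]
        assert r.top(2) == ["c", "a"]


class TestCompareRankings:
    @staticmethod
    def ranking(scores):
        return ImportanceRanking(scope="t", scores=scores)

    def test_identical_rho_one(self):
        r = self.ranking({"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5})
        rho, p = compare_rankings(r, r)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)  # 2 of 4! orderings reach |rho|=1

    def test_reversed_rho_minus_one(self):
        r1 = self.ranking({"a": 3.0, "b": 2.0, "c": 1.0})
        r2 = self.ranking({"a": 1.0, "b": 2.0, "c": 3.0})
        rho, _ = compare_rankings(r1, r2)
        assert rho == pytest.approx(-1.0)

    def test_worked_example_rho_08(self):
        # ranks (1,2,3,4,5) vs (2,1,4,3,5): rho = 1 - 6*4/(5*24) = 0.8
        r1 = self.ranking({"a": 5, "b": 4, "c": 3, "d": 2, "e": 1})
        r2 = self.ranking({"a": 4, "b": 5, "c": 2, "d": 3, "e": 1})
        rho, p = compare_rankings(r1, r2)
        assert rho == pytest.approx(0.8)
        # exact two-sided permutation p-value over 5! orderings
        exact = np.mean(
            [
                abs(stats.pearsonr(perm, [1, 2, 3, 4, 5])[0]) >= 0.8 - 1e-12
                for perm in __import__("itertools").permutations([2, 1, 4, 3, 5])
            ]
        )
        assert p == pytest.approx(exact)

    def test_large_intersection_uses_t_approximation(self, rng):
        names = [f"f{i}" for i in range(25)]
        s1 = {f: float(v) for f, v in zip(names, rng.random(25))}
        s2 = {f: float(v) for f, v in zip(names, rng.random(25))}
        rho, p = compare_rankings(self.ranking(s1), self.ranking(s2))
        expect = stats.spearmanr(
            [s1[f] for f in sorted(names)], [s2[f] for f in sorted(names)]
        )
        assert rho == pytest.approx(float(expect.statistic), abs=1e-12)
        assert p == pytest.approx(float(expect.pvalue), abs=1e-12)

    def test_too_few_common_features_raise(self):
        r1 = self.ranking({"a": 1.0, "b": 0.5})
        r2 = self.ranking({"a": 1.0, "c": 0.5})
        with pytest.raises(ValueError, match="common features"):
            compare_rankings(r1, r2)

    def test_compare_all_table(self):
        rankings = {
            "global": self.ranking({"a": 3.0, "b": 2.0, "c": 1.0}),
            "AD": self.ranking({"a": 3.0, "b": 2.0, "c": 1.0}),
            "MCI": self.ranking({"a": 1.0, "b": 2.0}),  # too small -> NaN
        }
        table = compare_all_rankings(rankings)
        assert len(table) == 3
        row = table[(table.ranking_a == "global") & (table.ranking_b == "AD")]
        assert row.rho.iloc[0] == pytest.approx(1.0)
        assert table.rho.isna().sum() == 2


class TestPlotData:
    def test_waterfall_contract(self):
        expl = make_expl({"a": 0.3, "b": -0.1, "c": 0.05}, baseline=0.4)
        df = waterfall_data(expl, top_k=2)
        assert list(df.feature) == ["a", "b", "(rest)"]
        assert df.phi.iloc[2] == pytest.approx(0.05)
        assert df.attrs["baseline"] + df.phi.sum() == pytest.approx(
            df.attrs["prediction"]
        )

    def test_waterfall_topk_covers_all(self):
        expl = make_expl({"a": 0.3, "b": -0.1}, baseline=0.4)
        df = waterfall_data(expl, top_k=10)
        assert df.phi.iloc[-1] == pytest.approx(0.0)
        with pytest.raises(ValueError, match="top_k"):
            waterfall_data(expl, top_k=0)

    def test_beeswarm_long_format(self):
        expls = [make_expl({"a": 0.1, "b": 0.2}, subject_id=f"s{i}")
                 for i in range(3)]
        df = beeswarm_data(expls)
        assert len(df) == 6
        assert set(df.columns) >= {"model_scope", "subject_id", "feature",
                                   "phi", "feature_value"}

    def test_frame_roundtrip_fields(self):
        expls = [make_expl({"a": 0.1}, subject_id="s0", true_label="MCI")]
        df = explanations_to_frame(expls)
        assert df.true_label.iloc[0] == "MCI"
        assert df.baseline.iloc[0] == pytest.approx(0.4)
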