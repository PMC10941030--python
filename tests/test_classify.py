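"""Classification pipeline: pruning, ranking, AUC, Youden, repeated CV."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gamedx.classify import (ModelSpec, auc_roc, prune_correlated,
                             rank_importance, repeated_cv_evaluate, run_contrast,
                             select_top_k, youden_operating_point)


class TestPruneCorrelated:
    def test_duplicate_column_pruned(self, rng):
        x = rng.normal(size=50)
        m = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        retained = prune_correlated(m)
        assert len([c for c in retained if c in ("a", "b")]) == 1
        assert "c" in retained

    def test_uncorrelated_all_retained(self, rng):
        m = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        assert set(prune_correlated(m)) == {"a", "b", "c"}

    def test_result_satisfies_threshold(self, rng):
        base = rng.normal(size=(100, 3))
        m = pd.DataFrame({
            "a": base[:, 0], "b": base[:, 0] + 0.1 * base[:, 1],
            "c": base[:, 1], "d": base[:, 2]})
        retained = prune_correlated(m, threshold=0.5)
        corr = m[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.5 + 1e-12

    def test_matches_exhaustive_rule_on_toy(self, rng):
        """Greedy result equals a literal re-application of the rule."""
        base = rng.normal(size=(60, 2))
        m = pd.DataFrame({
            "a": base[:, 0], "b": 0.9 * base[:, 0] + 0.3 * rng.normal(size=60),
            "c": base[:, 1], "d": -base[:, 1] + 0.2 * rng.normal(size=60)})

        def literal(mat, thr=0.5):
            cols = list(mat.columns)
            while True:
                corr = mat[cols].corr().abs()
                np.fill_diagonal(corr.values, 0)
                if corr.values.max() <= thr:
                    return cols
                i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
                mean_i = corr.values[i].mean()
                mean_j = corr.values[j].mean()
                drop = cols[i] if mean_i > mean_j else cols[j] \
                    if mean_j > mean_i else cols[max(i, j)]
                cols.remove(drop)

        assert prune_correlated(m) == literal(m)

    def test_irp_exempt(self, rng):
        x = rng.normal(size=80)
        m = pd.DataFrame({"game_f": x, "age": x})  # perfectly correlated
        retained = prune_correlated(m)
        assert "age" in retained  # IRP never pruned


class TestRanking:
    def test_planted_signal_ranked_first(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        m = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"noise{i}" for i in range(10)])
        m["signal"] = y + 0.01 * rng.normal(size=n)
        for fam in ("elastic_net_logistic", "gradient_boosting", "random_forest"):
            ranked = rank_importance(m, y, ModelSpec(fam, seed=0))
            assert ranked[0] == "signal", fam

    def test_deterministic_under_seed(self, rng):
        n = 100
        y = rng.integers(0, 2, n)
        m = pd.DataFrame(rng.normal(size=(n, 8)),
                         columns=[f"f{i}" for i in range(8)])
        a = rank_importance(m, y, ModelSpec("random_forest", seed=5))
        b = rank_importance(m, y, ModelSpec("random_forest", seed=5))
        assert a == b

    def test_single_class_rejected(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            rank_importance(m, np.zeros(20, dtype=int), ModelSpec())

    @pytest.mark.parametrize("n_ranked,k,expected", [(25, 10, 10), (4, 10, 4)])
    def test_select_top_k(self, n_ranked, k, expected):
        ranked = [f"f{i}" for i in range(n_ranked)]
        assert select_top_k(ranked, k) == ranked[:expected]

    def test_select_top_k_empty_rejected(self):
        with pytest.raises(ValueError):
            select_top_k([], 10)

    def test_selection_recovery_planted_features(self, rng):
        """>=4 of 5 planted features reach the top-10 in >=90% of seeded runs."""
        hits = 0
        runs = 6
        for seed in range(runs):
            r = np.random.default_rng(seed)
            n = 300
            y = r.integers(0, 2, n)
            noise = r.normal(size=(n, 200))
            m = pd.DataFrame(noise, columns=[f"n{i}" for i in range(200)])
            for i in range(5):
                m[f"planted{i}"] = 1.5 * y + r.normal(size=n)
            ranked = rank_importance(m, y, ModelSpec("elastic_net_logistic",
                                                     seed=seed))
            top = set(select_top_k(ranked, 10))
            hits += sum(f"planted{i}" in top for i in range(5)) >= 4
        assert hits >= int(np.ceil(0.9 * runs))


def brute_force_auc(scores, labels):
    """Pairwise enumeration of concordant / tied positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
        ([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0], 0.875),  # 4-pair enumeration
        ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
    ])
    def test_examples(self, scores, labels, expected):
        assert auc_roc(scores, labels) == pytest.approx(expected)

    def test_matches_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            ours = auc_roc(scores, labels)
            assert ours == pytest.approx(brute_force_auc(scores, labels))
            assert ours == pytest.approx(roc_auc_score(labels, scores))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False),
                    min_size=4, max_size=20))
    def test_monotone_transform_invariance(self, scores):
        scores = [round(s, 3) for s in scores]  # keep exp() strictly monotone
        labels = [i % 2 for i in range(len(scores))]
        a = auc_roc(scores, labels)
        b = auc_roc([np.exp(s) for s in scores], labels)
        assert a == pytest.approx(b)

    def test_complement_under_negation(self, rng):
        scores = rng.normal(size=50)  # continuous: ties have measure zero
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert auc_roc(scores, labels) + auc_roc(-scores, labels) == \
            pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.9], [1, 1])


class TestYouden:
    def test_perfect_separation(self):
        thr, sens, spec = youden_operating_point(
            [0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert 0.3 < thr <= 0.8
        assert sens == 1.0 and spec == 1.0

    def test_exhaustive_scan_agreement(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 25))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            thr, sens, spec = youden_operating_point(scores, labels)
            best_j = max(
                np.mean(scores[labels == 1] >= t)
                + np.mean(scores[labels == 0] < t) - 1
                for t in np.unique(scores))
            assert sens + spec - 1 == pytest.approx(best_j)

    def test_worst_case_single_positive(self):
        thr, sens, spec = youden_operating_point(
            [0.05, 0.5, 0.6, 0.7], [1, 0, 0, 0])
        assert sens + spec - 1 == pytest.approx(0.0, abs=1e-12)


class TestRepeatedCV:
    def test_perfect_feature_all_repeats_auc_one(self, rng):
        n = 60
        y = np.array([0, 1] * (n // 2))
        m = pd.DataFrame({"perfect": y.astype(float),
                          "noise": rng.normal(size=n)})
        res = repeated_cv_evaluate(m, y, ModelSpec("elastic_net_logistic"),
                                   folds=5, repeats=3, seed=0)
        assert res.auc_roc == pytest.approx(1.0)
        assert all(a == pytest.approx(1.0) for a in res.per_repeat_auc)
        assert len(res.per_repeat_auc) == 3

    def test_null_labels_auc_near_half(self, rng):
        n = 200
        m = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"f{i}" for i in range(10)])
        y = rng.permutation([0] * 100 + [1] * 100)
        res = repeated_cv_evaluate(m, y, ModelSpec("elastic_net_logistic"),
                                   folds=10, repeats=10, seed=1)
        assert 0.4 <= res.auc_roc <= 0.6

    def test_folds_reduced_with_warning(self, rng):
        y = np.array([1] * 9 + [0] * 40)
        m = pd.DataFrame({"f": rng.normal(size=49)})
        with pytest.warns(UserWarning, match="reducing folds"):
            res = repeated_cv_evaluate(m, y, ModelSpec("gradient_boosting"),
                                       folds=10, repeats=2, seed=0)
        assert len(res.per_repeat_auc) == 2

    def test_single_class_rejected(self, rng):
        m = pd.DataFrame({"f": rng.normal(size=10)})
        with pytest.raises(ValueError):
            repeated_cv_evaluate(m, np.ones(10, dtype=int), ModelSpec())


class TestRunContrast:
    def test_game_signal_beats_irp(self, study):
        res = run_contrast(study["matrix"], study["cohort"], "both",
                           folds=5, repeats=2, seed=0)
        assert res["best"]["IRP_plus_game"].auc_roc > \
            res["best"]["IRP_only"].auc_roc
        assert len(res["best"]["IRP_plus_game"].selected_predictors) <= 10

    def test_empty_contrast_group_rejected(self, study):
        cohort = study["cohort"].copy()
        cohort = cohort[cohort["group"] != "-PNP+CD"]
        matrix = study["matrix"].loc[
            [i for i in study["matrix"].index if i in set(cohort["id"])]]
        with pytest.raises(ValueError):
            run_contrast(matrix, cohort, "cd_only", folds=3, repeats=1, seed=0)

    def test_single_family_single_row_per_scope(self, study):
        res = run_contrast(study["matrix"], study["cohort"], "pnp_only",
                           models=[ModelSpec("gradient_boosting", seed=0)],
                           folds=3, repeats=1, seed=0)
        assert len(res["table"]) == 2  # one family x two scopes
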