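"""Matching and association: SMD, cardinality matching, ORs, logistic models."""

import itertools

import numpy as np
import pandas as pd
import pytest

import gamedx as g
from gamedx.association import (ExposureSpec, MatchSpec, SeparationError,
                                association_analysis, cardinality_match,
                                fit_logistic, odds_ratio_2x2,
                                simulate_exposure_outcome,
                                standardized_mean_difference,
                                subgroup_analysis)


class TestSMD:
    def test_identical_groups_zero(self):
        v = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        assert standardized_mean_difference(
            v, [True] * 3 + [False] * 3, [False] * 3 + [True] * 3) == 0.0

    def test_unit_separation(self, rng):
        a = rng.normal(0, 1, 5000)
        b = rng.normal(1, 1, 5000)
        v = np.concatenate([a, b])
        mask_a = np.arange(10000) < 5000
        smd = standardized_mean_difference(v, mask_a, ~mask_a)
        assert smd == pytest.approx(1.0, abs=0.05)

    def test_hand_example(self):
        # A={1,2,3}, B={2,3,4}: |2-3| / sqrt((1+1)/2) = 1.0
        v = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]
        smd = standardized_mean_difference(
            v, [True] * 3 + [False] * 3, [False] * 3 + [True] * 3)
        assert smd == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            standardized_mean_difference([1.0], [True], [False])


def _toy_cohort(ages_a, ages_b):
    n = len(ages_a) + len(ages_b)
    return pd.DataFrame({
        "id": [f"P{i}" for i in range(n)],
        "age": list(ages_a) + list(ages_b),
        "outcome": [False] * len(ages_a) + [True] * len(ages_b)})


def brute_force_match(cohort, covariates, tol):
    """Exhaustive search over all equal-size subset pairs (tiny n only)."""
    a_idx = cohort.index[~cohort["outcome"]].tolist()
    b_idx = cohort.index[cohort["outcome"]].tolist()
    sd_pool = {}
    for c in covariates:
        v = cohort[c].to_numpy(dtype=float)
        va = np.var(v[a_idx], ddof=1) if len(a_idx) > 1 else 0.0
        vb = np.var(v[b_idx], ddof=1) if len(b_idx) > 1 else 0.0
        sd_pool[c] = np.sqrt((va + vb) / 2)
    best = 0
    for k in range(min(len(a_idx), len(b_idx)), 0, -1):
        for sa in itertools.combinations(a_idx, k):
            for sb in itertools.combinations(b_idx, k):
                ok = True
                for c in covariates:
                    v = cohort[c].to_numpy(dtype=float)
                    if sd_pool[c] == 0:
                        continue
                    smd = abs(v[list(sa)].mean() - v[list(sb)].mean()) / sd_pool[c]
                    if smd > tol:
                        ok = False
                        break
                if ok:
                    return k
        if best:
            break
    return 0


class TestCardinalityMatch:
    def test_balanced_cohort_fully_retained(self):
        cohort = _toy_cohort([60.0, 62, 64, 66, 68, 70, 72, 74, 76, 78],
                             [60.0, 62, 64, 66, 68, 70, 72, 74, 76, 78])
        res = cardinality_match(cohort, "outcome",
                                MatchSpec(covariates=("age",),
                                          exact_match_columns=()))
        assert res.status == "optimal"
        assert res.n_per_group == 10

    def test_unbalanced_sizes_equalized(self):
        cohort = _toy_cohort([60.0, 62, 64, 66, 68, 70, 72, 74, 76, 78, 61, 63],
                             [60.0, 62, 64, 66, 68, 70, 72, 74])
        res = cardinality_match(cohort, "outcome",
                                MatchSpec(covariates=("age",),
                                          exact_match_columns=()))
        assert res.status == "optimal"
        assert res.n_per_group == 8

    def test_matches_brute_force_on_toy_instance(self):
        """ILP solution equals exhaustive search with one extreme outlier."""
        cohort = _toy_cohort([55.0, 60, 62, 64, 66, 95],
                             [61.0, 63, 65, 67, 69, 71])
        spec = MatchSpec(covariates=("age",), smd_tolerance=0.1,
                         exact_match_columns=())
        res = cardinality_match(cohort, "outcome", spec)
        expected = brute_force_match(cohort, ("age",), 0.1)
        assert res.status == "optimal"
        assert res.n_per_group == expected
        for smd in res.smd_after.values():
            assert smd <= 0.1 + 1e-9

    def test_exact_match_constraint(self, study):
        cohort = study["cohort"]
        res = cardinality_match(cohort, "cd_label", MatchSpec())
        assert res.status == "optimal"
        sub = cohort[cohort["id"].isin(
            res.retained_ids["False"] + res.retained_ids["True"])]
        t1 = sub.groupby(sub["id"].isin(res.retained_ids["True"]))[
            "diabetes_type"].apply(lambda s: (s == 1).sum())
        assert t1.iloc[0] == t1.iloc[1]  # exact type-1 count balance

    def test_post_match_balance_on_study(self, study):
        res = cardinality_match(study["cohort"], "cd_label", MatchSpec())
        assert res.n_per_group > 0
        assert max(res.smd_after.values()) <= 0.1 + 1e-9

    def test_one_empty_group_infeasible(self):
        cohort = _toy_cohort([60.0, 62], [])
        res = cardinality_match(cohort, "outcome",
                                MatchSpec(covariates=("age",),
                                          exact_match_columns=()))
        assert res.status == "infeasible"
        assert res.n_per_group == 0


class TestOddsRatio2x2:
    def test_pre_matching_table(self):
        or_, lo, hi, corrected = odds_ratio_2x2(61, 28, 92, 80)
        assert round(or_, 2) == 1.89
        assert not corrected
        assert lo < or_ < hi

    def test_post_matching_table(self):
        or_, lo, hi, _ = odds_ratio_2x2(61, 28, 49, 40)
        assert round(or_, 2) == 1.78

    def test_unit_table(self):
        or_, lo, hi, _ = odds_ratio_2x2(1, 1, 1, 1)
        assert or_ == pytest.approx(1.0)

    def test_zero_cell_continuity_correction(self):
        or_, lo, hi, corrected = odds_ratio_2x2(5, 0, 3, 7)
        assert corrected
        assert np.isfinite(lo) and np.isfinite(hi)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(-1, 1, 1, 1)

    def test_woolf_ci_coverage_at_or2(self, rng):
        """Woolf 95% CI covers the true OR=2 in 93-97% of 500 tables."""
        covered = 0
        n = 200
        for i in range(500):
            df = simulate_exposure_outcome(n, 2.0, seed=10_000 + i)
            a = int(((df.exposure == 1) & (df.outcome == 1)).sum())
            b = int(((df.exposure == 0) & (df.outcome == 1)).sum())
            c = int(((df.exposure == 1) & (df.outcome == 0)).sum())
            d = int(((df.exposure == 0) & (df.outcome == 0)).sum())
            _, lo, hi, _ = odds_ratio_2x2(a, b, c, d)
            covered += lo <= 2.0 <= hi
        assert 0.93 * 500 <= covered <= 0.97 * 500


class TestFitLogistic:
    def test_univariate_matches_cross_product(self):
        df = pd.DataFrame({"x": [1] * 61 + [0] * 28 + [1] * 49 + [0] * 40,
                           "y": [1] * 89 + [0] * 89})
        res = fit_logistic(df["y"], df[["x"]])
        expected = odds_ratio_2x2(61, 28, 49, 40)[0]
        assert np.exp(res.coefficients[1]) == pytest.approx(expected, abs=1e-6)

    def test_cross_product_equivalence_fuzz(self, rng):
        """exp(univariate coefficient) == ad/bc over random 2x2 tables."""
        for _ in range(250):
            a, b, c, d = rng.integers(1, 60, size=4)
            x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            y = np.r_[np.ones(a + b), np.zeros(c + d)]
            res = fit_logistic(y, pd.DataFrame({"x": x}))
            assert np.exp(res.coefficients[1]) == pytest.approx(
                (a * d) / (b * c), rel=1e-6)

    def test_independent_predictor_or_one(self):
        df = pd.DataFrame({"x": [1, 0] * 40, "y": [1, 1, 0, 0] * 20})
        res = fit_logistic(df["y"], df[["x"]])
        assert np.exp(res.coefficients[1]) == pytest.approx(1.0, abs=1e-6)

    def test_separation_detected(self):
        df = pd.DataFrame({"x": [0.0] * 20 + [1.0] * 20,
                           "y": [0] * 20 + [1] * 20})
        with pytest.raises(SeparationError):
            fit_logistic(df["y"], df[["x"]])

    def test_ci_brackets_or(self):
        df = simulate_exposure_outcome(500, 2.0, seed=3)
        res = fit_logistic(df["outcome"], df[["exposure"]])
        assert (res.ci_low <= res.odds_ratios).all()
        assert (res.odds_ratios <= res.ci_high).all()


class TestAssociationAnalysis:
    def test_planted_or_recovered(self):
        """Model 1 recovers a generative OR of 2.0 at n=2000 within [1.7, 2.3]."""
        df = simulate_exposure_outcome(2000, 2.0, seed=5)
        table = association_analysis(df, ExposureSpec("exposure", "outcome", ()))
        m1 = table[(table.model == "model1") & (table.term == "exposure")]
        assert 1.7 <= float(m1.odds_ratio.iloc[0]) <= 2.3

    def test_empty_adjustment_model2_equals_model1(self):
        df = simulate_exposure_outcome(400, 1.5, seed=2)
        table = association_analysis(df, ExposureSpec("exposure", "outcome", ()))
        m1 = table[table.model == "model1"].odds_ratio.to_numpy()
        m2 = table[table.model == "model2"].odds_ratio.to_numpy()
        assert m1 == pytest.approx(m2)

    def test_single_level_exposure_degenerate(self):
        df = simulate_exposure_outcome(100, 1.0, seed=1)
        with pytest.warns(UserWarning, match="single level"):
            table = association_analysis(
                df, ExposureSpec("exposure", "outcome", (),
                                 categories=("only",)))
        assert (table.odds_ratio == 1.0).all()

    def test_four_models_on_study(self, study):
        cohort = study["cohort"]
        match = cardinality_match(cohort, "cd_label", MatchSpec())
        table = association_analysis(
            cohort, ExposureSpec("pnp_label", "cd_label"), matched=match)
        assert set(table.model) == {"model1", "model2", "model3", "model4"}
        pnp_rows = table[table.term == "pnp_label"]
        assert (pnp_rows.odds_ratio > 0).all()

    def test_categorized_exposure_reference_first(self, study):
        cohort = study["cohort"].copy()
        cohort["nds_band"] = cohort["nds"].map(
            lambda s: g.classify_severity(int(s), "NDS"))
        table = association_analysis(
            cohort, ExposureSpec("nds_band", "cd_label", (),
                                 categories=("normal", "mild", "moderate",
                                             "severe")))
        m1_terms = set(table[table.model == "model1"].term)
        assert "nds_band[normal]" not in m1_terms  # reference level omitted
        assert {"nds_band[mild]", "nds_band[moderate]",
                "nds_band[severe]"} <= m1_terms


class TestSubgroupAnalysis:
    def test_planted_female_only_effect(self):
        """A female-only OR=5 effect yields female OR > male OR."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 3000
            female = rng.random(n) < 0.5
            exposure = rng.random(n) < 0.5
            logit = -1.0 + np.where(female & exposure, np.log(5.0), 0.0)
            outcome = rng.random(n) < 1 / (1 + np.exp(-logit))
            df = pd.DataFrame({
                "id": [f"S{i}" for i in range(n)],
                "gender": np.where(female, "female", "male"),
                "exposure": exposure.astype(int),
                "outcome": outcome.astype(int)})
            res = subgroup_analysis(df, "gender",
                                    ExposureSpec("exposure", "outcome", ()))
            get_or = lambda lvl: float(res[lvl]["table"].query(
                "model == 'model1' and term == 'exposure'").odds_ratio.iloc[0])
            hits += get_or("female") > get_or("male")
        assert hits >= 5 * 0.95 - 1  # >=95% of seeds, allowing one miss

    def test_small_stratum_flagged(self):
        df = simulate_exposure_outcome(105, 1.5, seed=4)
        df["stratum"] = ["rare"] * 5 + ["common"] * 100
        res = subgroup_analysis(df, "stratum",
                                ExposureSpec("exposure", "outcome", ()))
        assert res["rare"]["unstable"]
        assert not res["common"]["unstable"]
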