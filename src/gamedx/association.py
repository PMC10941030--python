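"""Cardinality matching and odds-ratio association analysis.

Cardinality matching selects the largest equal-size subsets of the two
outcome groups such that every covariate's standardized mean difference
(SMD) stays below a tolerance (default 0.1).  The selection is solved as an
integer linear program (HiGHS via ``scipy.optimize.milp``); SMD denominators
are frozen to the pre-match pooled SD, which keeps the balance constraints
linear and is the conventional reporting choice.

The association stage mirrors a four-model odds-ratio layout: Model 1/3 are
univariate logistic fits of the outcome on the exposure before/after
matching, Model 2/4 additionally adjust for the six profile covariates.
Univariate ORs on a binary exposure coincide with the 2x2 cross-product
ratio; confidence intervals are Wald/Woolf on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm as _norm

DEFAULT_COVARIATES = ("gender", "age", "weight", "bmi", "diabetes_type",
                      "diabetes_duration")


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MatchSpec:
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    smd_tolerance: float = 0.1
    exact_match_columns: tuple[str, ...] = ("diabetes_type",)

    def __post_init__(self) -> None:
        if self.smd_tolerance <= 0:
            raise ValueError("smd_tolerance must be positive")


@dataclass
class MatchResult:
    retained_ids: dict[str, list]
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    status: str  # optimal | greedy_fallback | infeasible

    @property
    def n_per_group(self) -> int:
        sizes = {len(v) for v in self.retained_ids.values()}
        assert len(sizes) <= 1, "retained groups must be equal-sized"
        return sizes.pop() if sizes else 0


@dataclass
class LogisticModelResult:
    model_label: str
    terms: list[str]
    coefficients: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "coef": self.coefficients,
            "odds_ratio": self.odds_ratios, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_value": self.p_values,
            "model": self.model_label})


@dataclass(frozen=True)
class ExposureSpec:
    exposure: str
    outcome: str = "cd_label"
    adjustment: tuple[str, ...] = DEFAULT_COVARIATES
    categories: tuple | None = None  # optional level order, first = reference


# ---------------------------------------------------------------------------
# Balance metrics and cardinality matching
# ---------------------------------------------------------------------------

def standardized_mean_difference(values, mask_a, mask_b) -> float:
    """|mean_A - mean_B| / sqrt((var_A + var_B) / 2) with sample variances.

    Binary columns use the same pooled-variance form on the indicator.
    """
    v = np.asarray(values, dtype=float)
    a, b = v[np.asarray(mask_a)], v[np.asarray(mask_b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    va = np.var(a, ddof=1) if len(a) > 1 else 0.0
    vb = np.var(b, ddof=1) if len(b) > 1 else 0.0
    denom = np.sqrt((va + vb) / 2.0)
    diff = abs(a.mean() - b.mean())
    if denom == 0:
        return 0.0 if diff == 0 else np.inf
    return float(diff / denom)


def _numeric_covariate(cohort: pd.DataFrame, col: str) -> np.ndarray:
    s = cohort[col]
    if s.dtype == object or s.dtype == bool:
        levels = sorted(s.unique(), key=str)
        if len(levels) > 2:
            raise ValueError(f"covariate {col} has >2 non-numeric levels")
        return (s == levels[-1]).to_numpy(dtype=float)
    return s.to_numpy(dtype=float)


def cardinality_match(cohort: pd.DataFrame, outcome_col: str,
                      spec: MatchSpec | None = None) -> MatchResult:
    """Maximum-cardinality 1:1 matching under SMD balance constraints.

    Selects equal-size subsets of the outcome=False and outcome=True groups
    maximizing the retained count subject to, for every covariate,
    |sum_A z x - sum_B z x| <= tol * sd_pool * n_selected (linear in the
    selection indicators), plus exact count constraints on the
    ``exact_match_columns`` levels.  Falls back to iterative greedy dropping
    when the solver fails, flagged in ``status``.
    """
    spec = spec or MatchSpec()
    y = cohort[outcome_col].astype(bool).to_numpy()
    ids = cohort["id"].to_numpy()
    n = len(cohort)
    group_a, group_b = ~y, y  # controls, cases
    if group_a.sum() == 0 or group_b.sum() == 0:
        return MatchResult({"False": [], "True": []}, {}, {}, "infeasible")

    covs = {c: _numeric_covariate(cohort, c) for c in spec.covariates}
    smd_before = {c: standardized_mean_difference(v, group_a, group_b)
                  for c, v in covs.items()}
    # frozen pre-match pooled SD per covariate
    sd_pool = {}
    for c, v in covs.items():
        va = np.var(v[group_a], ddof=1) if group_a.sum() > 1 else 0.0
        vb = np.var(v[group_b], ddof=1) if group_b.sum() > 1 else 0.0
        sd_pool[c] = float(np.sqrt((va + vb) / 2.0))

    sel = _solve_ilp(covs, sd_pool, group_a, group_b, cohort, spec)
    status = "optimal"
    if sel is None:
        sel = _greedy_match(covs, sd_pool, group_a, group_b, spec)
        status = "greedy_fallback"
    if sel is None or sel.sum() == 0:
        return MatchResult({"False": [], "True": []}, smd_before, {}, "infeasible")

    sel_a, sel_b = sel & group_a, sel & group_b
    smd_after = {}
    for c, v in covs.items():
        diff = abs(v[sel_a].mean() - v[sel_b].mean())
        smd_after[c] = float(diff / sd_pool[c]) if sd_pool[c] > 0 else 0.0
    return MatchResult(
        retained_ids={"False": sorted(ids[sel_a].tolist()),
                      "True": sorted(ids[sel_b].tolist())},
        smd_before=smd_before, smd_after=smd_after, status=status)


def _solve_ilp(covs, sd_pool, group_a, group_b, cohort, spec):
    try:
        from scipy.optimize import LinearConstraint, milp
        from scipy.optimize import Bounds
    except ImportError:  # pragma: no cover
        return None
    n = len(group_a)
    sign = np.where(group_a, 1.0, -1.0)  # +1 controls, -1 cases
    constraints = [LinearConstraint(sign, 0.0, 0.0)]  # equal group sizes
    in_a = group_a.astype(float)
    for c, v in covs.items():
        eps = spec.smd_tolerance * sd_pool[c]
        if sd_pool[c] == 0:
            continue
        # sum_A v x - sum_B v x - eps * n_A(x) <= 0  (and the mirror image);
        # n_A(x) = n_B(x) by the equal-size constraint
        row_plus = sign * v - eps * in_a
        row_minus = -sign * v - eps * in_a
        constraints.append(LinearConstraint(row_plus, -np.inf, 0.0))
        constraints.append(LinearConstraint(row_minus, -np.inf, 0.0))
    for c in spec.exact_match_columns:
        if c not in cohort.columns:
            continue
        v = _numeric_covariate(cohort, c)
        for level in np.unique(v):
            ind = (v == level).astype(float)
            constraints.append(LinearConstraint(sign * ind, 0.0, 0.0))
    res = milp(c=-np.ones(n), constraints=constraints,
               integrality=np.ones(n), bounds=Bounds(0.0, 1.0))
    if not res.success or res.x is None:
        return None
    return res.x > 0.5


def _greedy_match(covs, sd_pool, group_a, group_b, spec):
    """Iteratively drop the worst-imbalance member of the larger group."""
    sel = np.ones(len(group_a), dtype=bool)
    for _ in range(len(sel)):
        sel_a, sel_b = sel & group_a, sel & group_b
        na, nb = sel_a.sum(), sel_b.sum()
        if na == 0 or nb == 0:
            return None
        worst, worst_c = 0.0, None
        for c, v in covs.items():
            if sd_pool[c] == 0:
                continue
            smd = abs(v[sel_a].mean() - v[sel_b].mean()) / sd_pool[c]
            if smd > worst:
                worst, worst_c = smd, c
        if na == nb and worst <= spec.smd_tolerance:
            return sel
        if na != nb:
            larger = sel_a if na > nb else sel_b
        else:
            larger = sel_a if covs[worst_c][sel_a].mean() > covs[worst_c][sel_b].mean() \
                else sel_b
        v = covs[worst_c] if worst_c else next(iter(covs.values()))
        idx = np.flatnonzero(larger)
        other = sel_b if larger is sel_a else sel_a
        target = v[other].mean()
        drop = idx[np.argmax(np.abs(v[idx] - target))]
        sel[drop] = False
    return None


# ---------------------------------------------------------------------------
# Odds ratios and logistic models
# ---------------------------------------------------------------------------

def odds_ratio_2x2(a: int, b: int, c: int, d: int,
                   alpha: float = 0.05) -> tuple[float, float, float, bool]:
    """Cross-product OR with the Woolf log-SE confidence interval.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls.  Zero cells get a 0.5 continuity correction, flagged in the
    returned boolean.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    corrected = any(x == 0 for x in cells)
    if corrected:
        a, b, c, d = (x + 0.5 for x in cells)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(_norm.ppf(1 - alpha / 2))
    lo = float(np.exp(np.log(or_) - z * se))
    hi = float(np.exp(np.log(or_) + z * se))
    return float(or_), lo, hi, corrected


def fit_logistic(outcome, predictors: pd.DataFrame,
                 model_label: str = "model", max_iter: int = 100) -> LogisticModelResult:
    """Maximum-likelihood logistic regression (IRLS) with Wald 95% CIs.

    Raises :class:`SeparationError` when a predictor perfectly separates the
    outcome and :class:`ConvergenceError` when IRLS fails to converge.
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(predictors.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial())
            fit = model.fit(maxiter=max_iter, tol=1e-10)
        except sm.tools.sm_exceptions.PerfectSeparationWarning as exc:
            raise SeparationError(str(exc)) from exc
        except sm.tools.sm_exceptions.PerfectSeparationError as exc:
            raise SeparationError(str(exc)) from exc
    coefs = fit.params.to_numpy()
    if np.any(np.abs(coefs[1:]) > 15):
        culprit = X.columns[1:][np.argmax(np.abs(coefs[1:]))]
        raise SeparationError(f"predictor {culprit!r} separates the outcome")
    if not np.all(np.isfinite(fit.bse)):
        raise ConvergenceError(f"IRLS failed within {max_iter} iterations")
    ci = fit.conf_int()
    return LogisticModelResult(
        model_label=model_label, terms=list(X.columns),
        coefficients=coefs, odds_ratios=np.exp(coefs),
        ci_low=np.exp(ci[0].to_numpy()), ci_high=np.exp(ci[1].to_numpy()),
        p_values=fit.pvalues.to_numpy(), n=len(y))


def _design(cohort: pd.DataFrame, spec: ExposureSpec) -> pd.DataFrame:
    """Exposure design columns; categorized exposures use the first stage as
    reference."""
    s = cohort[spec.exposure]
    if spec.categories is not None:
        levels = list(spec.categories)
        if len(levels) < 2:
            warnings.warn(f"exposure {spec.exposure} has a single level; "
                          "returning reference-only design", stacklevel=2)
            return pd.DataFrame(index=cohort.index)
        return pd.DataFrame(
            {f"{spec.exposure}[{lv}]": (s == lv).astype(float)
             for lv in levels[1:]}, index=cohort.index)
    if s.dtype == bool or set(s.unique()) <= {0, 1, True, False}:
        return pd.DataFrame({spec.exposure: s.astype(float)}, index=cohort.index)
    return pd.DataFrame({spec.exposure: s.astype(float)}, index=cohort.index)


def association_analysis(cohort: pd.DataFrame, exposure: ExposureSpec,
                         matched: MatchResult | None = None) -> pd.DataFrame:
    """Model 1-4 odds-ratio table for an exposure-outcome pair.

    Model 1/2 use the full cohort (univariate / covariate-adjusted); Model
    3/4 repeat both on the matched subcohort when a match result is given.
    """
    frames = []
    datasets = [("model1", cohort, False), ("model2", cohort, True)]
    if matched is not None:
        keep = set(matched.retained_ids["False"]) | set(matched.retained_ids["True"])
        sub = cohort[cohort["id"].isin(keep)]
        datasets += [("model3", sub, False), ("model4", sub, True)]
    for label, data, adjust in datasets:
        design = _design(data, exposure)
        if design.shape[1] == 0:
            frames.append(pd.DataFrame(
                [{"term": f"{exposure.exposure}[ref]", "coef": 0.0,
                  "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                  "p_value": np.nan, "model": label}]))
            continue
        if adjust:
            adj = [c for c in exposure.adjustment if c != exposure.exposure]
            for c in adj:
                design[c] = _numeric_covariate(data, c)
        res = fit_logistic(data[exposure.outcome].astype(float), design, label)
        frame = res.as_frame()
        frames.append(frame[frame["term"] != "const"])
    return pd.concat(frames, ignore_index=True)


def subgroup_analysis(cohort: pd.DataFrame, stratifier: str,
                      exposure: ExposureSpec, min_size: int = 20) -> dict:
    """Per-stratum association tables; small strata are flagged unstable."""
    out = {}
    for level in sorted(cohort[stratifier].unique(), key=str):
        sub = cohort[cohort[stratifier] == level]
        entry = {"table": None, "n": len(sub),
                 "unstable": len(sub) < min_size, "error": None}
        try:
            entry["table"] = association_analysis(sub, exposure)
        except (SeparationError, ConvergenceError, ValueError) as exc:
            entry["error"] = str(exc)
            entry["unstable"] = True
        out[str(level)] = entry
    return out


# ---------------------------------------------------------------------------
# Synthetic generator with a planted odds ratio (for recovery checks)
# ---------------------------------------------------------------------------

def simulate_exposure_outcome(n: int, odds_ratio: float,
                              baseline_prob: float = 0.3,
                              exposure_prob: float = 0.5,
                              seed: int = 0) -> pd.DataFrame:
    """Binary exposure/outcome pairs with a known generative odds ratio."""
    rng = np.random.default_rng(seed)
    exposure = rng.random(n) < exposure_prob
    logit0 = np.log(baseline_prob / (1 - baseline_prob))
    logits = logit0 + np.log(odds_ratio) * exposure
    outcome = rng.random(n) < 1 / (1 + np.exp(-logits))
    return pd.DataFrame({"id": [f"S{i}" for i in range(n)],
                         "exposure": exposure.astype(int),
                         "outcome": outcome.astype(int)})
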