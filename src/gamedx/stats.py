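"""Descriptive statistics and normality-gated group comparisons.

Continuous variables are tested with a t-test (two groups) or one-way ANOVA
(more groups) when every group passes Shapiro-Wilk normality at alpha=0.05,
and with Mann-Whitney U or Kruskal-Wallis H otherwise; categorical
variables with a chi-square test.  Multiple comparisons are corrected with
the Holm-Bonferroni step-down procedure.  Summaries report mean (SD) for
normal and median (IQR, Q3-Q1) for non-normal variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

NORMALITY_ALPHA = 0.05


@dataclass
class GroupTestResult:
    variable: str
    groups: tuple[str, ...]
    test_name: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def prevalence(flags) -> tuple[int, float]:
    """(count, proportion) of true flags; rounding happens at presentation."""
    flags = list(flags)
    if not flags:
        raise ValueError("prevalence of an empty list is undefined")
    n = int(sum(bool(f) for f in flags))
    return n, n / len(flags)


def holm_adjust(p_values) -> list[float]:
    """Holm-Bonferroni step-down adjustment, input order preserved.

    p_(i) (sorted ascending) is multiplied by (m - i), running maxima
    enforce monotonicity, and values are capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def _is_normal(values: np.ndarray) -> bool:
    if len(values) < 3 or np.ptp(values) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(values).pvalue > NORMALITY_ALPHA


def _mann_whitney(a: np.ndarray, b: np.ndarray):
    # exact p for small tie-free samples, normal approximation (with tie
    # correction) otherwise
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    return sps.mannwhitneyu(a, b, alternative="two-sided", method=method)


def compare_groups(values, group_labels, variable_kind: str,
                   variable: str = "", yates: bool = False) -> GroupTestResult:
    """Compare a variable between groups with the normality-gated test menu.

    ``values``/``group_labels`` are aligned sequences; missing values are
    dropped pairwise.  Categorical variables use chi-square on the
    contingency table (Yates correction off by default for 2x2).
    """
    values = pd.Series(list(values))
    labels = pd.Series(list(group_labels))
    ok = values.notna() & labels.notna()
    values, labels = values[ok], labels[ok]
    group_names = tuple(sorted(labels.unique(), key=str))
    if len(group_names) < 2:
        raise ValueError("need at least two non-empty groups")

    if variable_kind == "categorical":
        table = pd.crosstab(values, labels)
        if table.shape[0] < 2:
            stat, p = 0.0, 1.0  # variable constant: no association testable
        else:
            correction = yates and table.shape == (2, 2)
            stat, p, _, _ = sps.chi2_contingency(table.values, correction=correction)
        summaries = {g: {str(v): int(c) for v, c in table[g].items()}
                     for g in table.columns}
        return GroupTestResult(variable, group_names, "chi_square",
                               float(stat), float(min(p, 1.0)), summaries=summaries)

    groups = [values[labels == g].astype(float).to_numpy() for g in group_names]
    small = [g for g in groups if len(g) < 3]
    if small:
        warnings.warn("group with <3 observations: falling back to the "
                      "nonparametric branch", stacklevel=2)
        all_normal = False
    else:
        all_normal = all(_is_normal(g) for g in groups)

    summaries = {}
    for name, g in zip(group_names, groups):
        if all_normal:
            summaries[name] = {"mean": float(np.mean(g)),
                               "sd": float(np.std(g, ddof=1)) if len(g) > 1 else 0.0}
        else:
            q1, q3 = np.percentile(g, [25, 75]) if len(g) else (np.nan, np.nan)
            summaries[name] = {"median": float(np.median(g)),
                               "iqr": float(q3 - q1)}

    if len(groups) == 2:
        a, b = groups
        if np.array_equal(np.sort(a), np.sort(b)):
            test = "t_test" if all_normal else "mann_whitney"
            return GroupTestResult(variable, group_names, test, 0.0, 1.0,
                                   summaries=summaries)
        if all_normal:
            res = sps.ttest_ind(a, b)
            return GroupTestResult(variable, group_names, "t_test",
                                   float(res.statistic), float(res.pvalue),
                                   summaries=summaries)
        res = _mann_whitney(a, b)
        return GroupTestResult(variable, group_names, "mann_whitney",
                               float(res.statistic), float(min(res.pvalue, 1.0)),
                               summaries=summaries)
    if all_normal:
        res = sps.f_oneway(*groups)
        return GroupTestResult(variable, group_names, "anova",
                               float(res.statistic), float(res.pvalue),
                               summaries=summaries)
    if np.ptp(np.concatenate(groups)) == 0:
        return GroupTestResult(variable, group_names, "kruskal_wallis", 0.0, 1.0,
                               summaries=summaries)
    res = sps.kruskal(*groups)
    return GroupTestResult(variable, group_names, "kruskal_wallis",
                           float(res.statistic), float(res.pvalue),
                           summaries=summaries)


def correlation(x, y, method: str = "auto") -> tuple[float, float]:
    """(r, p) by Pearson, Spearman, or the normality-gated automatic choice.

    Pairs with a missing member are deleted first.  ``auto`` picks Pearson
    iff both variables pass Shapiro-Wilk at alpha=0.05, else Spearman.
    """
    x = pd.Series(list(x), dtype=float)
    y = pd.Series(list(y), dtype=float)
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if method == "auto":
        method = "pearson" if (_is_normal(x) and _is_normal(y)) else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


#: Variables summarized in the four-group cohort report.
_TABLE1_VARIABLES = (
    ("gender", "categorical"), ("age", "continuous"), ("weight", "continuous"),
    ("bmi", "continuous"), ("diabetes_type", "categorical"),
    ("diabetes_duration", "continuous"), ("nss", "continuous"),
    ("nds", "continuous"), ("moca_raw", "continuous"),
)


def summarize_cohort(cohort: pd.DataFrame, group_col: str = "group",
                     variables=_TABLE1_VARIABLES) -> pd.DataFrame:
    """Per-variable summaries and group-comparison p-values.

    One row per (variable, group) summary plus the test p-value, in
    deterministic order — the structure of a cohort characteristics table.
    """
    if cohort[group_col].nunique() < 2:
        raise ValueError("group column needs at least two levels")
    rows = []
    for var, kind in variables:
        res = compare_groups(cohort[var], cohort[group_col], kind, variable=var)
        for g in res.groups:
            n_g = int((cohort[group_col] == g).sum())
            rows.append({"variable": var, "group": g, "n": n_g,
                         "summary": _format_summary(res.summaries.get(g, {})),
                         "test": res.test_name,
                         "p_value": round(res.p_value, 4)})
    return pd.DataFrame(rows)


def _format_summary(s: dict) -> str:
    if "mean" in s:
        return f"{s['mean']:.1f} ({s['sd']:.1f})"
    if "median" in s:
        return f"{s['median']:.1f} ({s['iqr']:.1f})"
    return "; ".join(f"{k}: {v}" for k, v in s.items())
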