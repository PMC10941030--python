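"""Correlation-pruned, importance-ranked, repeated-CV classification.

The model-development stage for the three group contrasts against the
unimpaired reference group (-PNP-CD):

1. drop game features until all pairwise |r| <= 0.5 (greedy, IRP exempt);
2. rank the survivors by a classifier-family-specific importance measure
   averaged over an internal 5-fold split;
3. keep the top ten as final predictors;
4. evaluate with stratified 10-fold cross-validation repeated 10 times;
   the reported AUC-ROC is the mean of the per-repeat AUCs, and
   sensitivity/specificity come from the Youden-optimal threshold on the
   pooled out-of-fold scores.

Model families: elastic-net logistic (GLMNET-style), gradient boosting,
random forest, SVM and plain penalized logistic regression via a registry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import IRP_COLUMNS

REFERENCE_GROUP = "-PNP-CD"
CONTRAST_GROUPS = {"pnp_only": "+PNP-CD", "cd_only": "-PNP+CD", "both": "+PNP+CD"}


@dataclass(frozen=True)
class ContrastSpec:
    positive_group: str
    feature_scope: str = "IRP_plus_game"  # IRP_only | IRP_plus_game
    reference_group: str = REFERENCE_GROUP

    def __post_init__(self) -> None:
        if self.reference_group != REFERENCE_GROUP:
            raise ValueError("the reference group is fixed to the unimpaired group")
        if self.feature_scope not in ("IRP_only", "IRP_plus_game"):
            raise ValueError(f"unknown feature scope {self.feature_scope!r}")


@dataclass(frozen=True)
class ModelSpec:
    family: str = "elastic_net_logistic"
    hyperparameters: tuple = ()
    seed: int = 0


@dataclass
class EvaluationResult:
    contrast: str
    family: str
    scope: str
    selected_predictors: list[str]
    auc_roc: float
    sensitivity: float
    specificity: float
    threshold: float
    per_repeat_auc: list[float]
    seed: int


def _make_estimator(spec: ModelSpec, seed: int):
    hp = dict(spec.hyperparameters)
    fam = spec.family
    if fam == "elastic_net_logistic":
        clf = LogisticRegression(solver="saga",
                                 l1_ratio=hp.get("l1_ratio", 0.5),
                                 C=hp.get("C", 1.0), max_iter=2000, tol=1e-3,
                                 random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)]), "linear"
    if fam == "penalized_logistic":
        clf = LogisticRegression(l1_ratio=0.0, C=hp.get("C", 1.0),
                                 max_iter=5000, random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)]), "linear"
    if fam == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 2),
            learning_rate=hp.get("learning_rate", 0.1),
            random_state=seed), "tree"
    if fam == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 200),
            random_state=seed), "tree"
    if fam == "svm":
        clf = SVC(kernel="linear", C=hp.get("C", 1.0), probability=False,
                  random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)]), "linear"
    raise ValueError(f"unknown model family {spec.family!r}")


def _scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def prune_correlated(matrix: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Greedy elimination of highly inter-correlated features.

    While any pair has |r| > threshold, the member of the worst pair with
    the larger mean absolute correlation to all remaining features is
    dropped (ties: the later catalogue column goes).  IRP columns are exempt
    and always retained.  The result satisfies max pairwise |r| <= threshold.
    """
    game_cols = [c for c in matrix.columns if c not in IRP_COLUMNS]
    irp_cols = [c for c in matrix.columns if c in IRP_COLUMNS]
    if len(game_cols) <= 1:
        return game_cols + irp_cols
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = matrix[game_cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    alive = np.ones(len(game_cols), dtype=bool)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], corr, 0.0)
        worst = sub.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        mean_i = sub[i, alive].mean()
        mean_j = sub[j, alive].mean()
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)  # tie: later catalogue order dropped
        alive[drop] = False
    retained = [c for c, a in zip(game_cols, alive) if a]
    return retained + irp_cols


def rank_importance(matrix: pd.DataFrame, labels, model: ModelSpec) -> list[str]:
    """Features in descending importance, averaged over a 5-fold split.

    Linear families use absolute standardized coefficients, tree families
    total impurity-based split gain.  Ties break by column name for a
    deterministic order.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to rank importance")
    X = matrix.to_numpy(dtype=float)
    n_splits = min(5, np.bincount(y).min())
    importance = np.zeros(matrix.shape[1])
    if n_splits < 2:
        folds = [(np.arange(len(y)), None)]
    else:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=model.seed % (2 ** 31))
        folds = [(tr, None) for tr, _ in skf.split(X, y)]
    for tr, _ in folds:
        est, kind = _make_estimator(model, model.seed % (2 ** 31))
        est.fit(X[tr], y[tr])
        if kind == "linear":
            clf = est.named_steps["clf"] if isinstance(est, Pipeline) else est
            importance += np.abs(np.ravel(clf.coef_))
        else:
            importance += est.feature_importances_
    order = sorted(range(matrix.shape[1]),
                   key=lambda i: (-importance[i], matrix.columns[i]))
    return [matrix.columns[i] for i in order]


def select_top_k(ranked: list[str], k: int = 10) -> list[str]:
    """The top-``k`` ranked variables (all of them when fewer are ranked)."""
    if not ranked:
        raise ValueError("ranked feature list is empty")
    return ranked[:max(0, k)]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc_roc(scores, labels) -> float:
    """AUC by the Mann-Whitney pair count: (concordant + ties/2) / (n+ n-)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
                 / (len(pos) * len(neg)))


def youden_operating_point(scores, labels) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing Youden's J.

    All observed scores are candidate thresholds (predict positive at
    score >= threshold); ties on J resolve to the lowest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    best = None
    for thr in np.unique(s):
        pred = s >= thr
        sens = np.mean(pred[y == 1])
        spec = np.mean(~pred[y == 0])
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    return float(thr), float(sens), float(spec)


# ---------------------------------------------------------------------------
# Repeated cross-validation and the contrast driver
# ---------------------------------------------------------------------------

def repeated_cv_evaluate(matrix: pd.DataFrame, labels, model: ModelSpec,
                         folds: int = 10, repeats: int = 10,
                         seed: int = 0, contrast: str = "",
                         scope: str = "") -> EvaluationResult:
    """Stratified k-fold CV repeated ``repeats`` times, fully seeded.

    Out-of-fold scores are pooled within each repeat for a per-repeat AUC;
    the reported AUC is their mean.  Sensitivity/specificity come from the
    Youden point on the scores pooled over all repeats.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    min_class = int(np.bincount(y).min())
    if min_class < folds:
        warnings.warn(f"reducing folds from {folds} to {min_class} "
                      "(smallest class size)", stacklevel=2)
        folds = min_class
    X = matrix.to_numpy(dtype=float)
    per_repeat = []
    pooled_scores, pooled_labels = [], []
    for r in range(repeats):
        rseed = (seed * 1000 + r) % (2 ** 31)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rseed)
        oof = np.empty(len(y))
        for tr, te in skf.split(X, y):
            est, _ = _make_estimator(model, rseed)
            est.fit(X[tr], y[tr])
            oof[te] = _scores(est, X[te])
        per_repeat.append(auc_roc(oof, y))
        pooled_scores.append(oof)
        pooled_labels.append(y)
    thr, sens, spec = youden_operating_point(
        np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return EvaluationResult(
        contrast=contrast, family=model.family, scope=scope,
        selected_predictors=list(matrix.columns),
        auc_roc=float(np.mean(per_repeat)), sensitivity=sens,
        specificity=spec, threshold=thr,
        per_repeat_auc=[float(a) for a in per_repeat], seed=seed)


def run_contrast(matrix: pd.DataFrame, cohort: pd.DataFrame,
                 contrast: str, models: list[ModelSpec] | None = None,
                 folds: int = 10, repeats: int = 10, seed: int = 0,
                 top_k: int = 10, prune_threshold: float = 0.5
                 ) -> dict:
    """Full model-development pipeline for one group contrast.

    Subsets the feature matrix to the contrast's two groups, runs the
    IRP-only evaluation (six covariates, no selection) and the IRP+game
    pipeline (prune -> rank -> top-k -> repeated CV) for every model family,
    and returns the best result per scope plus the per-family table.
    """
    positive = CONTRAST_GROUPS.get(contrast, contrast)
    models = models or [ModelSpec("elastic_net_logistic", seed=seed),
                        ModelSpec("gradient_boosting", seed=seed)]
    groups = cohort.set_index("id")["group"]
    ids = [i for i in matrix.index if groups.get(i) in (REFERENCE_GROUP, positive)]
    if not ids:
        raise ValueError(f"no participants in contrast {contrast!r}")
    sub = matrix.loc[ids]
    y = (groups.loc[ids] == positive).astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"contrast {contrast!r} has an empty group")

    results: list[EvaluationResult] = []
    irp = sub[[c for c in IRP_COLUMNS if c in sub.columns]]
    for m in models:
        results.append(repeated_cv_evaluate(
            irp, y, m, folds, repeats, seed, contrast=contrast, scope="IRP_only"))
    retained = prune_correlated(sub, prune_threshold)
    pruned = sub[retained]
    for m in models:
        ranked = rank_importance(pruned, y, m)
        predictors = select_top_k(ranked, top_k)
        results.append(repeated_cv_evaluate(
            pruned[predictors], y, m, folds, repeats, seed,
            contrast=contrast, scope="IRP_plus_game"))

    table = pd.DataFrame([{
        "contrast": r.contrast, "scope": r.scope, "family": r.family,
        "auc_roc": r.auc_roc, "sensitivity": r.sensitivity,
        "specificity": r.specificity} for r in results])
    best = {}
    for scope in ("IRP_only", "IRP_plus_game"):
        scoped = [r for r in results if r.scope == scope]
        best[scope] = max(scoped, key=lambda r: r.auc_roc)
    return {"best": best, "table": table, "results": results}
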