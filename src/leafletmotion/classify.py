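"""Severity classification from leaflet motion metrics.

Two tasks mirror the clinical questions:

* **binary_significant_AS** — significant (moderate-or-worse) stenosis vs
  control, from the eight motion metrics alone;
* **multiclass_severity** — control vs moderate vs severe, with the
  interventricular septal and posterior wall diameters added (both are
  routinely measured in the same PLAX view).

Doppler-derived fields (AVA, gradients, velocity, dimensionless index)
never enter the feature set: the point is prediction without hemodynamic
assessment.

Protocol: collinearity filter at |r| > 0.9, stratified 80:20 train/test
split, 5-fold stratified cross-validated grid search maximizing CV AUC
(one-vs-rest mean for the multiclass task), refit at the best grid point,
and evaluation on the untouched holdout. Standardization is fit on the
training set only (inside a Pipeline) for the elastic-net and k-NN models;
the random forest consumes raw features.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .stats import holm_adjust

TASK1_FEATURES = ("ld_mid", "ld_tip", "ld_global", "ad_mid", "ad_tip",
                  "ad_global", "linearity", "flexibility")
TASK2_FEATURES = TASK1_FEATURES + ("ivsd", "pwd")
TASKS = ("binary_significant_AS", "multiclass_severity")
FAMILIES = ("elastic_net_logistic", "k_nearest_neighbors", "random_forest")
SEVERITY_ORDER = ("control", "moderate", "severe")


def default_grid(family: str) -> list[dict]:
    """Conventional tuning grids, ordered so ties resolve toward the
    more conservative model (stronger penalty, larger k, fewer split
    candidates)."""
    if family == "elastic_net_logistic":
        cs = np.logspace(-2, 2, 12)
        return [{"C": float(c), "l1_ratio": l1}
                for c in cs for l1 in (0.1, 0.3, 0.5, 0.7, 0.9)]
    if family == "k_nearest_neighbors":
        return [{"n_neighbors": k} for k in range(25, 2, -2)]
    if family == "random_forest":
        return [{"max_features": mf} for mf in (2, 3, "sqrt")]
    raise ValueError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    task: str
    seed: int = 0
    tuning_grid: tuple = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if not self.tuning_grid:
            object.__setattr__(self, "tuning_grid",
                               tuple(default_grid(self.family)))


@dataclass
class FittedModel:
    spec: ModelSpec
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    classes: tuple
    best_params: dict
    cv_summary: pd.DataFrame


@dataclass
class EvalReport:
    task: str
    family: str
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    roc_points: dict[str, pd.DataFrame]
    confusion_matrix: pd.DataFrame
    importance: pd.DataFrame | None
    cv_summary: pd.DataFrame
    per_class_auc: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        return {"task": self.task, "family": self.family, "auc": self.auc,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "ppv": self.ppv,
                "npv": self.npv, "per_class_auc": self.per_class_auc}


# ---------------------------------------------------------------------------
# feature table


def build_feature_table(cohort_df: pd.DataFrame, task: str
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix and outcome for a task; refuses missing values."""
    if task == "binary_significant_AS":
        features = list(TASK1_FEATURES)
        y = cohort_df["severity"].isin(["moderate", "severe"]).astype(int)
        y.name = "significant_as"
    elif task == "multiclass_severity":
        features = list(TASK2_FEATURES)
        y = pd.Series(pd.Categorical(cohort_df["severity"],
                                     categories=SEVERITY_ORDER, ordered=True),
                      index=cohort_df.index, name="severity")
    else:
        raise ValueError(f"unknown task {task!r}")
    x = cohort_df[features].copy()
    if x.isna().any().any():
        bad = x[x.isna().any(axis=1)]
        ident = (cohort_df.loc[bad.index, "patient_id"].tolist()
                 if "patient_id" in cohort_df else bad.index.tolist())
        cols = x.columns[x.isna().any()].tolist()
        raise ValueError(f"missing values in {cols} for record(s) {ident}")
    x.index = cohort_df.index
    return x, y


def remove_collinear(features: pd.DataFrame, threshold: float = 0.9
                     ) -> tuple[list[str], list[str]]:
    """Iteratively drop one member of each |r| > threshold pair.

    While any absolute pairwise correlation exceeds the threshold, the
    worst pair is found and the member with the larger mean absolute
    correlation against all remaining features is dropped; ties break by
    feature-name order (the later name is dropped).
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    kept = list(features.columns)
    dropped: list[str] = []
    while len(kept) >= 2:
        corr = features[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        if corr.loc[worst] <= threshold:
            break
        a, b = worst
        mean_a = corr.loc[a].drop(b).mean() if len(kept) > 2 else corr.loc[a, b]
        mean_b = corr.loc[b].drop(a).mean() if len(kept) > 2 else corr.loc[a, b]
        if math.isclose(mean_a, mean_b, rel_tol=0, abs_tol=1e-12):
            victim = max(a, b)
        else:
            victim = a if mean_a > mean_b else b
        kept.remove(victim)
        dropped.append(victim)
    return kept, dropped


def stratified_split(x: pd.DataFrame, y: pd.Series,
                     test_fraction: float = 0.2, seed: int = 0
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Outcome-stratified train/test split (disjoint, exhaustive)."""
    counts = y.value_counts()
    if (counts < 5).any():
        small = counts[counts < 5].index.tolist()
        raise ValueError(f"outcome level(s) {small} have < 5 records; "
                         "cannot stratify")
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, stratify=y, random_state=seed)
    return x_tr, x_te, y_tr, y_te


# ---------------------------------------------------------------------------
# tuning and fitting


def _make_estimator(spec: ModelSpec, params: dict):
    if spec.family == "elastic_net_logistic":
        est = LogisticRegression(
            solver="saga", max_iter=10000, tol=1e-4,
            random_state=spec.seed, **params)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.family == "k_nearest_neighbors":
        est = KNeighborsClassifier(weights="uniform", **params)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    est = RandomForestClassifier(n_estimators=500, max_depth=None,
                                 random_state=spec.seed, **params)
    return Pipeline([("model", est)])


def _cv_auc(proba: np.ndarray, y_true: np.ndarray, classes: np.ndarray) -> float:
    if len(classes) == 2:
        return roc_auc_score(y_true, proba[:, 1])
    aucs = [roc_auc_score((y_true == c).astype(int), proba[:, i])
            for i, c in enumerate(classes)]
    return float(np.mean(aucs))


def tune_and_fit(spec: ModelSpec, x_train: pd.DataFrame, y_train: pd.Series
                 ) -> FittedModel:
    """5-fold stratified CV grid search on mean (one-vs-rest) AUC, then refit.

    Selection is discrimination-first but calibration-aware: among grid
    points whose mean CV AUC lies within one standard error of the best
    (the CV AUC surface is typically a near-flat ridge, where raw argmax
    amounts to picking fold noise and can land on probability-degenerate
    over-shrunk models), the point with the lowest mean CV log-loss wins.
    Remaining exact ties resolve to the earliest grid point, and grids are
    ordered conservative-first (stronger penalty, larger k, fewer split
    candidates).
    """
    from sklearn.metrics import log_loss

    y = np.asarray(y_train)
    classes = np.unique(y)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=spec.seed)
    folds = list(cv.split(np.zeros(len(y)), y))
    for _, (_, test_idx) in enumerate(folds):
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("degenerate CV fold with a single class")
    rows = []
    for params in spec.tuning_grid:
        fold_aucs, fold_losses = [], []
        for tr_idx, te_idx in folds:
            est = _make_estimator(spec, params)
            est.fit(x_train.iloc[tr_idx], y[tr_idx])
            proba = est.predict_proba(x_train.iloc[te_idx])
            fold_aucs.append(_cv_auc(proba, y[te_idx], est.classes_))
            fold_losses.append(log_loss(y[te_idx], proba, labels=classes))
        rows.append({"params": dict(params),
                     "mean_cv_auc": float(np.mean(fold_aucs)),
                     "mean_cv_logloss": float(np.mean(fold_losses)),
                     "fold_aucs": fold_aucs})
    aucs = np.array([r["mean_cv_auc"] for r in rows])
    top = int(np.argmax(aucs))
    se = float(np.std(rows[top]["fold_aucs"], ddof=1)
               / math.sqrt(len(rows[top]["fold_aucs"])))
    candidates = [i for i, a in enumerate(aucs) if a >= aucs[top] - se]
    best_idx = min(candidates, key=lambda i: (rows[i]["mean_cv_logloss"], i))
    best_params = dict(spec.tuning_grid[best_idx])
    pipeline = _make_estimator(spec, best_params)
    pipeline.fit(x_train, y)
    return FittedModel(spec=spec, pipeline=pipeline,
                       feature_names=tuple(x_train.columns),
                       classes=tuple(pipeline.classes_),
                       best_params=best_params,
                       cv_summary=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# evaluation


def _binary_confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray
                              ) -> tuple[float, float, float, float]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    return sens, spec, ppv, npv


def evaluate(fitted: FittedModel, x_test: pd.DataFrame, y_test: pd.Series,
             threshold: float = 0.5) -> EvalReport:
    """Holdout evaluation.

    Binary: rank-statistic ROC/AUC on predicted probabilities, confusion
    metrics at the probability threshold (default 0.5). Multiclass:
    per-class one-vs-rest ROC/AUC with their unweighted mean, argmax
    confusion matrix, macro-averaged sensitivity / specificity / PPV / NPV.
    """
    y = np.asarray(y_test)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class test set cannot be evaluated")
    proba = fitted.pipeline.predict_proba(x_test[list(fitted.feature_names)])
    classes = list(fitted.classes)
    roc_points: dict[str, pd.DataFrame] = {}
    if len(classes) == 2:
        p1 = proba[:, 1]
        auc = float(roc_auc_score(y, p1))
        fpr, tpr, thr = roc_curve(y, p1)
        roc_points["positive"] = pd.DataFrame(
            {"fpr": fpr, "tpr": tpr, "threshold": thr})
        y_pred = (p1 >= threshold).astype(int)
        accuracy = float(np.mean(y_pred == y))
        sens, spec, ppv, npv = _binary_confusion_metrics(y, y_pred)
        cm = pd.crosstab(pd.Series(y, name="true"),
                         pd.Series(y_pred, name="predicted"), dropna=False)
        per_class_auc = {"positive": auc}
    else:
        per_class_auc = {}
        for i, cls in enumerate(classes):
            y_bin = (y == cls).astype(int)
            per_class_auc[str(cls)] = float(roc_auc_score(y_bin, proba[:, i]))
            fpr, tpr, thr = roc_curve(y_bin, proba[:, i])
            roc_points[str(cls)] = pd.DataFrame(
                {"fpr": fpr, "tpr": tpr, "threshold": thr})
        auc = float(np.mean(list(per_class_auc.values())))
        y_pred = np.asarray(classes)[np.argmax(proba, axis=1)]
        accuracy = float(np.mean(y_pred == y))
        sens_l, spec_l, ppv_l, npv_l = [], [], [], []
        for cls in classes:
            s, sp, pv, nv = _binary_confusion_metrics(
                (y == cls).astype(int), (y_pred == cls).astype(int))
            sens_l.append(s); spec_l.append(sp); ppv_l.append(pv); npv_l.append(nv)
        sens, spec = float(np.nanmean(sens_l)), float(np.nanmean(spec_l))
        ppv, npv = float(np.nanmean(ppv_l)), float(np.nanmean(npv_l))
        cm = pd.crosstab(pd.Series(y, name="true"),
                         pd.Series(y_pred, name="predicted"), dropna=False)
    try:
        importance = feature_importance(fitted)
    except ValueError:
        importance = None
    return EvalReport(task=fitted.spec.task, family=fitted.spec.family,
                      auc=auc, accuracy=accuracy, sensitivity=float(sens),
                      specificity=float(spec), ppv=float(ppv), npv=float(npv),
                      roc_points=roc_points, confusion_matrix=cm,
                      importance=importance, cv_summary=fitted.cv_summary,
                      per_class_auc=per_class_auc)


# ---------------------------------------------------------------------------
# model comparison


def _delong_components(y: np.ndarray, scores: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and structural components (V10 per positive, V01 per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    all_scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(all_scores)
    pos_ranks = ranks[:m]
    auc = (pos_ranks.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (pos_ranks - sps.rankdata(pos)) / n
    v01 = 1.0 - (ranks[m:] - sps.rankdata(neg)) / m
    return float(auc), v10, v01


def delong_test(y_true: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray
                ) -> tuple[float, float]:
    """DeLong test for two correlated ROC curves; returns (auc_a - auc_b, p)."""
    y = np.asarray(y_true).astype(int)
    auc_a, v10_a, v01_a = _delong_components(y, np.asarray(scores_a, float))
    auc_b, v10_b, v01_b = _delong_components(y, np.asarray(scores_b, float))
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return diff, 1.0 if diff == 0 else 0.0
    z = diff / math.sqrt(var)
    return diff, float(2 * sps.norm.sf(abs(z)))


def _bootstrap_ovr_auc_test(y: np.ndarray, proba_a: np.ndarray,
                            proba_b: np.ndarray, classes: Sequence,
                            n_boot: int = 2000, seed: int = 0) -> float:
    """Stratified bootstrap p-value for a difference in mean one-vs-rest AUC."""
    rng = np.random.default_rng(seed)
    idx_by_class = [np.flatnonzero(y == c) for c in classes]

    def mean_ovr(p: np.ndarray, yy: np.ndarray) -> float:
        aucs = []
        for i, c in enumerate(classes):
            yb = (yy == c).astype(int)
            if yb.min() == yb.max():
                continue
            aucs.append(roc_auc_score(yb, p[:, i]))
        return float(np.mean(aucs))

    observed = mean_ovr(proba_a, y) - mean_ovr(proba_b, y)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(ix, size=len(ix), replace=True)
                              for ix in idx_by_class])
        diffs[b] = mean_ovr(proba_a[idx], y[idx]) - mean_ovr(proba_b[idx], y[idx])
    if observed == 0:
        return 1.0
    # two-sided: how often the bootstrap difference crosses zero
    frac = min(np.mean(diffs <= 0), np.mean(diffs >= 0))
    return float(min(1.0, 2 * frac))


def compare_models(y_true: np.ndarray,
                   probas: Mapping[str, np.ndarray],
                   task: str, classes: Sequence | None = None,
                   seed: int = 0) -> dict:
    """Pairwise performance comparison on common predictions.

    Binary task: DeLong test per model pair. Multiclass: stratified
    bootstrap (2000 resamples) of the difference in mean one-vs-rest AUC.
    The global p is the Holm-adjusted minimum across pairs.
    """
    names = list(probas.keys())
    y = np.asarray(y_true)
    for name, p in probas.items():
        if len(p) != len(y):
            raise ValueError(f"model {name}: prediction length mismatch")
    pairwise = []
    for a, b in itertools.combinations(names, 2):
        if task == "binary_significant_AS":
            pa = probas[a][:, 1] if probas[a].ndim == 2 else probas[a]
            pb = probas[b][:, 1] if probas[b].ndim == 2 else probas[b]
            diff, p = delong_test(y, pa, pb)
        else:
            if classes is None:
                classes = sorted(np.unique(y))
            diff = np.nan
            p = _bootstrap_ovr_auc_test(y, probas[a], probas[b], classes,
                                        seed=seed)
        pairwise.append({"pair": (a, b), "auc_diff": diff, "p": p})
    if len(names) == 1 or not pairwise:
        return {"pairwise": pairwise, "global_p": 1.0}
    adjusted = holm_adjust([r["p"] for r in pairwise])
    for r, pa in zip(pairwise, adjusted):
        r["p_adjusted"] = pa
    return {"pairwise": pairwise, "global_p": float(min(adjusted))}


# ---------------------------------------------------------------------------
# feature importance


def feature_importance(fitted: FittedModel,
                       method: str = "coefficients") -> pd.DataFrame:
    """Ranked feature importance, normalized so the top feature scores 1.

    Elastic net: absolute standardized coefficients (multinomial: summed
    across classes). Random forest: impurity-based importance. Permutation
    importance is available for any family via ``method="permutation"``
    (computed on the training pipeline's stored data is not retained, so
    permutation requires passing data; see ``permutation_importance``).
    """
    if method != "coefficients":
        raise ValueError("use permutation_importance() for permutation scores")
    model = fitted.pipeline.named_steps["model"]
    if isinstance(model, LogisticRegression):
        if not hasattr(model, "coef_"):
            raise ValueError("model is not fitted")
        scores = np.sum(np.abs(model.coef_), axis=0)
    elif isinstance(model, RandomForestClassifier):
        if not hasattr(model, "feature_importances_"):
            raise ValueError("model is not fitted")
        scores = np.asarray(model.feature_importances_, dtype=float)
    else:
        raise ValueError(f"no coefficient importance for {fitted.spec.family}")
    top = scores.max()
    if top > 0:
        scores = scores / top
    df = pd.DataFrame({"feature": fitted.feature_names, "importance": scores})
    return (df.sort_values(["importance", "feature"],
                           ascending=[False, True])
            .reset_index(drop=True))


def permutation_importance_scores(fitted: FittedModel, x: pd.DataFrame,
                                  y: pd.Series, n_repeats: int = 20,
                                  seed: int = 0) -> pd.DataFrame:
    """Permutation importance on held-out data, normalized to max 1."""
    from sklearn.inspection import permutation_importance

    res = permutation_importance(
        fitted.pipeline, x[list(fitted.feature_names)], y,
        n_repeats=n_repeats, random_state=seed, scoring="accuracy")
    scores = np.maximum(res.importances_mean, 0.0)
    if scores.max() > 0:
        scores = scores / scores.max()
    df = pd.DataFrame({"feature": fitted.feature_names, "importance": scores})
    return (df.sort_values(["importance", "feature"], ascending=[False, True])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# end-to-end convenience


def run_task(cohort_df: pd.DataFrame, task: str, family: str,
             seed: int = 0, test_fraction: float = 0.2,
             collinearity_threshold: float = 0.9,
             tuning_grid: tuple = ()) -> tuple[FittedModel, EvalReport]:
    """Full protocol for one (task, family): features → filter → split →
    tune → holdout evaluation."""
    x, y = build_feature_table(cohort_df, task)
    kept, _ = remove_collinear(x, threshold=collinearity_threshold)
    x = x[kept]
    x_tr, x_te, y_tr, y_te = stratified_split(x, y, test_fraction, seed)
    spec = ModelSpec(family=family, task=task, seed=seed,
                     tuning_grid=tuple(tuning_grid))
    fitted = tune_and_fit(spec, x_tr, y_tr)
    report = evaluate(fitted, x_te, y_te)
    return fitted, report
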