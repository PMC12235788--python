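"""Cohort statistics: group tests, correlation, reliability, power.

Implements the analysis stage applied to the motion metrics: Kruskal–Wallis
omnibus tests across severity classes (chosen over ANOVA because the class
variances are strongly unequal), Games–Howell pairwise post-hoc comparisons
with Holm–Bonferroni adjustment within each metric's three-pair family,
Pearson correlation of motion metrics with aortic valve area, two-way
random-effects intraclass correlation for inter- and intra-rater
reliability, a descriptive per-class table, and a Monte-Carlo power
analysis of the omnibus test.

The omnibus, chi-square and correlation tests wrap scipy; Games–Howell,
ICC(2,1) and its F-based confidence interval are implemented here from the
mean-squares / studentized-range formulas.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .geometry import METRIC_NAMES
from .simulate import ClassParams, SEVERITIES, moment_match_lognormal


@dataclass(frozen=True)
class OmnibusResult:
    """Tie-corrected Kruskal–Wallis H test across >= 2 groups."""

    statistic: float
    df: int
    p_value: float
    group_ns: tuple[int, ...]
    group_mean_ranks: tuple[float, ...]


@dataclass(frozen=True)
class PairwiseResult:
    """One Games–Howell comparison, Holm-adjusted within its family."""

    pair: tuple[str, str]
    mean_diff: float
    t_statistic: float
    df: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""

    icc: float
    ci_low: float
    ci_high: float
    mode: str
    n_subjects: int
    n_raters: int


def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]] |
                   Sequence[Sequence[float]]) -> OmnibusResult:
    """Kruskal–Wallis rank sum test with midranks and tie correction."""
    groups, _ = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = sps.rankdata(pooled)
    ns = [len(g) for g in groups]
    splits = np.cumsum(ns)[:-1]
    mean_ranks = [float(r.mean()) for r in np.split(ranks, splits)]
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    return OmnibusResult(statistic=float(h), df=len(groups) - 1,
                         p_value=float(p), group_ns=tuple(ns),
                         group_mean_ranks=tuple(mean_ranks))


def games_howell(values_by_group: Mapping[str, Sequence[float]] |
                 Sequence[Sequence[float]]) -> list[PairwiseResult]:
    """Games–Howell pairwise comparisons for unequal variances and sizes.

    For each pair: Welch-type t on the two variance terms, Welch–
    Satterthwaite degrees of freedom, and a p-value from the studentized
    range distribution with k groups evaluated at ``|t| * sqrt(2)``. Holm
    adjustment is applied across the family of all pairs.
    """
    groups, names = _as_groups(values_by_group)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    stats = []
    for g, name in zip(groups, names):
        if len(g) < 2:
            raise ValueError(f"group {name}: need n >= 2")
        stats.append((float(np.mean(g)), float(np.var(g, ddof=1)), len(g)))
    results = []
    for i, j in itertools.combinations(range(k), 2):
        mi, vi, ni = stats[i]
        mj, vj, nj = stats[j]
        se2 = vi / ni + vj / nj
        if se2 == 0.0:
            if mi == mj:
                results.append((names[i], names[j], 0.0, 0.0, float(ni + nj - 2), 1.0))
                continue
            raise ValueError(
                f"pair ({names[i]}, {names[j]}): zero variance in both groups "
                "with unequal means")
        t = (mi - mj) / math.sqrt(se2)
        df = se2 ** 2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
        p_raw = float(sps.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
        results.append((names[i], names[j], mi - mj, t, df, min(1.0, p_raw)))
    p_adj = holm_adjust([r[5] for r in results])
    return [PairwiseResult(pair=(a, b), mean_diff=d, t_statistic=t, df=df,
                           p_raw=p, p_adjusted=pa)
            for (a, b, d, t, df, p), pa in zip(results, p_adj)]


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm–Bonferroni adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(x) for x in multipletests(p, method="holm")[1]]


def chi_square_independence(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(counts)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or np.any(table < 0):
            raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has an all-zero margin")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pearson_correlation(x: Sequence[float], y: Sequence[float]
                        ) -> tuple[float, float]:
    """Sample Pearson r with its t-transform p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def icc_two_way(ratings, mode: str = "interrater", alpha: float = 0.05
                ) -> ICCResult:
    """ICC(2,1) with its 95% F-based confidence interval.

    ``ratings`` is a complete subjects × raters matrix. The two-way
    random-effects, absolute-agreement, single-measure form is standard for
    interrater reliability of continuous echocardiographic measurements.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("incomplete ratings matrix")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 1.0

    if mse == 0.0 and msc == 0.0:
        lo, hi = icc, icc
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isinf(a):
            lo = hi = 1.0
        else:
            v = ((a * msc + b * mse) ** 2
                 / ((a * msc) ** 2 / (k - 1)
                    + (b * mse) ** 2 / ((n - 1) * (k - 1))))
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f1 * mse)
                  / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f2 * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f2 * msr))
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     mode=mode, n_subjects=n, n_raters=k)


def icc_analysis(metrics_df: pd.DataFrame, base_rater: str = "R1"
                 ) -> dict[str, dict]:
    """Inter- and intra-rater reliability from a metrics table with replicates.

    Expects columns patient_id, rater_id, replicate and the eight metrics.
    Interrater pairs the base rater's first measurement with a second
    rater's; intrarater pairs the base rater's first and second replicates.
    Returns per-metric ICCResults plus the unweighted mean ICC per mode.
    """
    out: dict[str, dict] = {}
    base = metrics_df[(metrics_df.rater_id == base_rater)
                      & (metrics_df.replicate == 1)].set_index("patient_id")
    other_raters = sorted(set(metrics_df.rater_id) - {base_rater})
    repeat = metrics_df[(metrics_df.rater_id == base_rater)
                        & (metrics_df.replicate == 2)].set_index("patient_id")
    second = (metrics_df[metrics_df.rater_id.isin(other_raters)]
              .set_index("patient_id") if other_raters else pd.DataFrame())
    for mode, partner in (("interrater", second), ("intrarater", repeat)):
        if partner.empty:
            continue
        shared = base.index.intersection(partner.index)
        per_metric = {}
        for metric in METRIC_NAMES:
            mat = np.column_stack([base.loc[shared, metric].to_numpy(),
                                   partner.loc[shared, metric].to_numpy()])
            per_metric[metric] = icc_two_way(mat, mode=mode)
        out[mode] = {
            "per_metric": per_metric,
            "mean_icc": float(np.mean([r.icc for r in per_metric.values()])),
            "n_subjects": int(len(shared)),
        }
    return out


# ---------------------------------------------------------------------------
# descriptive table

_CONTINUOUS_ROWS = [
    ("Age (yr)", "age"),
    ("Linear displacement, midpoint (mm)", "ld_mid"),
    ("Linear displacement, tip (mm)", "ld_tip"),
    ("Linear displacement, averaged (mm)", "ld_global"),
    ("Angular displacement, midpoint (deg)", "ad_mid"),
    ("Angular displacement, tip (deg)", "ad_tip"),
    ("Angular displacement, averaged (deg)", "ad_global"),
    ("Linearity (deg)", "linearity"),
    ("Flexibility (deg)", "flexibility"),
    ("Aortic valve area (cm2)", "ava"),
    ("Mean gradient (mmHg)", "mean_gradient"),
    ("Peak velocity (m/sec)", "peak_velocity"),
    ("Dimensionless index", "dimensionless_index"),
    ("Left ventricular ejection fraction (%)", "lvef"),
]


def descriptive_table(cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean ± SD (or n (%) for sex) with omnibus p-values.

    One row per characteristic; columns Overall / one per class present /
    p_value. Continuous rows use Kruskal–Wallis, the sex row a Pearson
    chi-square; with a single class the p column is NA.
    """
    if cohort_df.empty:
        raise ValueError("empty cohort")
    classes = [s for s in SEVERITIES if s in set(cohort_df.severity)]
    rows = []

    def fmt(values: np.ndarray) -> str:
        return f"{np.mean(values):.2f} ± {np.std(values, ddof=1):.2f}"

    for label, col in _CONTINUOUS_ROWS:
        if col not in cohort_df.columns:
            continue
        row = {"characteristic": label,
               "overall": fmt(cohort_df[col].to_numpy())}
        groups = {}
        for cls in classes:
            vals = cohort_df.loc[cohort_df.severity == cls, col].to_numpy()
            row[cls] = fmt(vals)
            groups[cls] = vals
        row["p_value"] = (kruskal_wallis(groups).p_value
                          if len(classes) > 1 else np.nan)
        rows.append(row)

    if "sex" in cohort_df.columns:
        row = {"characteristic": "Sex, female"}
        n_all = len(cohort_df)
        f_all = int((cohort_df.sex == "F").sum())
        row["overall"] = f"{f_all} ({100 * f_all / n_all:.0f}%)"
        counts = []
        for cls in classes:
            sub = cohort_df[cohort_df.severity == cls]
            f = int((sub.sex == "F").sum())
            row[cls] = f"{f} ({100 * f / len(sub):.0f}%)"
            counts.append([f, len(sub) - f])
        row["p_value"] = (chi_square_independence(np.array(counts))[2]
                          if len(classes) > 1 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_with_ava(cohort_df: pd.DataFrame,
                         metrics: Sequence[str] = ("ld_global", "ad_global"),
                         ) -> dict[str, tuple[float, float]]:
    """Pearson correlation of each motion metric with aortic valve area."""
    return {m: pearson_correlation(cohort_df[m], cohort_df["ava"])
            for m in metrics}


def power_simulation(class_params: Mapping[str, ClassParams],
                     alpha: float = 0.05, target_power: float = 0.80,
                     n_grid: Sequence[int] = (30, 60, 90, 126, 150),
                     reps: int = 500, seed: int = 0,
                     feature: str = "ad_global",
                     ) -> tuple[pd.DataFrame, int | None]:
    """Monte-Carlo power of the Kruskal–Wallis omnibus test across class sizes.

    For each total n on the grid (equal allocation across the three
    classes), repeatedly draws the target feature from each class's
    moment-matched lognormal marginal and records the rejection rate.
    Returns the power curve and the smallest total n reaching the target
    (None if the grid never reaches it).
    """
    if reps < 200:
        raise ValueError("reps must be >= 200 for a stable power estimate")
    rng = np.random.default_rng(seed)
    ln_params = {sev: moment_match_lognormal(*class_params[sev].params[feature])
                 for sev in SEVERITIES}
    rows = []
    minimal_n = None
    for total_n in n_grid:
        base, extra = divmod(total_n, len(SEVERITIES))
        ns = [base + (1 if i < extra else 0) for i in range(len(SEVERITIES))]
        rejections = 0
        for _ in range(reps):
            groups = [np.exp(mu + sigma * rng.standard_normal(n))
                      for (mu, sigma), n in zip(ln_params.values(), ns)]
            if kruskal_wallis(groups).p_value < alpha:
                rejections += 1
        power = rejections / reps
        rows.append({"total_n": total_n, "power": power})
        if minimal_n is None and power >= target_power:
            minimal_n = total_n
    return pd.DataFrame(rows), minimal_n


def pairwise_tests_by_metric(cohort_df: pd.DataFrame,
                             metrics: Sequence[str] = METRIC_NAMES,
                             ) -> pd.DataFrame:
    """Games–Howell pairwise tests per metric, Holm-adjusted within metric."""
    rows = []
    classes = [s for s in SEVERITIES if s in set(cohort_df.severity)]
    for metric in metrics:
        groups = {cls: cohort_df.loc[cohort_df.severity == cls, metric].to_numpy()
                  for cls in classes}
        for res in games_howell(groups):
            rows.append({"metric": metric, "pair": f"{res.pair[0]}-{res.pair[1]}",
                         "mean_diff": res.mean_diff, "t": res.t_statistic,
                         "df": res.df, "p_raw": res.p_raw,
                         "p_adjusted": res.p_adjusted})
    return pd.DataFrame(rows)


def _as_groups(values_by_group) -> tuple[list[np.ndarray], list[str]]:
    if isinstance(values_by_group, Mapping):
        names = list(values_by_group.keys())
        groups = [np.asarray(values_by_group[n], dtype=float) for n in names]
    else:
        groups = [np.asarray(g, dtype=float) for g in values_by_group]
        names = [str(i) for i in range(len(groups))]
    return groups, names
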