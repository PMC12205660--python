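"""Discrimination and agreement statistics.

Implements the evaluation stack used throughout: Mann-Whitney AUC, stepwise
average precision, exact Clopper-Pearson binomial intervals, the DeLong
placement-value test for correlated AUCs, relative-improvement arithmetic,
contingency-table tests (Yates-corrected chi-square, and the Fisher dialect
whose two-tailed p doubles the smaller one-tailed probability, capped at
one), and per-subgroup reporting.  pCR is the positive event everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise DataError("labels must be binary")
    return y


def roc_auc(scores, labels) -> float:
    """AUC by the Mann-Whitney concordance formulation (ties count 1/2)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise DataError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes are required for AUC")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def youden_threshold(scores, labels) -> float:
    """Threshold (score >= t is positive) maximizing sensitivity +
    specificity - 1; ties resolved toward the smallest threshold."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    cand = np.unique(s)
    best_t, best_j = float(cand[0]), -np.inf
    n_pos = max(y.sum(), 1)
    n_neg = max((1 - y).sum(), 1)
    for t in cand:
        pred = s >= t
        j = (pred & (y == 1)).sum() / n_pos + ((~pred) & (y == 0)).sum() / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def average_precision(scores, labels) -> float:
    """Stepwise AP = sum (R_i - R_{i-1}) P_i over descending-score
    thresholds, with tied scores grouped into a single threshold."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0:
        raise DataError("at least one positive is required for AP")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # group boundaries where the (descending) score changes
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, len(s) - 1)
    cum_tp = np.cumsum(y)[ends]
    cum_n = ends + 1
    precision = cum_tp / cum_n
    recall = cum_tp / y.sum()
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev_recall) * precision).sum())


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles."""
    k, n = int(successes), int(trials)
    if n == 0:
        raise DataError("trials must be positive")
    if not 0 <= k <= n:
        raise DataError("successes must lie in [0, trials]")
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


# ---- DeLong ---------------------------------------------------------------


def _placements(scores: np.ndarray, y: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) for a single model."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return auc, float(var)


def delong_ci(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    auc, var = delong_variance(scores, labels)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return auc, (float(auc - half), float(auc + half))


def delong_test(scores_a, scores_b, labels, alpha: float = 0.05) -> dict:
    """Compare the AUCs of two models scored on the same cases."""
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) != len(y):
        raise DataError("paired scores must have equal length")
    va10, va01 = _placements(a, y)
    vb10, vb01 = _placements(b, y)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    m, n = len(va10), len(va01)
    s10 = np.cov(np.stack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        z, p = 0.0, 1.0
        ci = (diff, diff)
    else:
        se = float(np.sqrt(var_diff))
        z = diff / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        zq = stats.norm.ppf(1.0 - alpha / 2.0)
        ci = (diff - zq * se, diff + zq * se)
    return {"auc_a": auc_a, "auc_b": auc_b, "delta": diff, "z": float(z),
            "p": float(p), "ci": (float(ci[0]), float(ci[1]))}


def ap_bootstrap_ci(scores, labels, alpha: float = 0.05, reps: int = 2000,
                    seed: int = 0) -> tuple[float, float]:
    """Stratified bootstrap CI for average precision (the AP interval method
    is not standard; this package uses a seeded class-stratified bootstrap)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.nonzero(y == 1)[0], np.nonzero(y == 0)[0]
    vals = np.empty(reps)
    for r in range(reps):
        idx = np.concatenate([rng.choice(pos_idx, len(pos_idx)),
                              rng.choice(neg_idx, len(neg_idx))])
        vals[r] = average_precision(s[idx], y[idx])
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


# ---- thresholded metrics ---------------------------------------------------


@dataclass
class MetricsReport:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    ap: float | None = None
    ap_ci: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _ratio_ci(k: int, n: int, alpha: float):
    if n == 0:
        return float("nan"), (0.0, 1.0)
    return k / n, clopper_pearson(k, n, alpha)


def confusion_metrics(pred_labels, true_labels, threshold: float = 0.5,
                      alpha: float = 0.05) -> MetricsReport:
    """Confusion-matrix metrics with exact Clopper-Pearson intervals."""
    y = _check_binary(true_labels)
    p = np.asarray(pred_labels).astype(int)
    if len(p) != len(y):
        raise DataError("prediction and label vectors must have equal length")
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    n = len(y)
    acc, acc_ci = _ratio_ci(tp + tn, n, alpha)
    sens, sens_ci = _ratio_ci(tp, tp + fn, alpha)
    spec, spec_ci = _ratio_ci(tn, tn + fp, alpha)
    ppv, ppv_ci = _ratio_ci(tp, tp + fp, alpha)
    npv, npv_ci = _ratio_ci(tn, tn + fn, alpha)
    flags = []
    if tp + fn == 0:
        flags.append("no positives")
    if tn + fp == 0:
        flags.append("no negatives")
    return MetricsReport(
        threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=acc, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        accuracy_ci=acc_ci, sensitivity_ci=sens_ci, specificity_ci=spec_ci,
        ppv_ci=ppv_ci, npv_ci=npv_ci, flags=flags,
    )


def metrics_report(scores, labels, threshold: float | None = None,
                   alpha: float = 0.05, ap_reps: int = 2000,
                   seed: int = 0) -> MetricsReport:
    """Full report: AUC/AP with CIs plus thresholded confusion metrics.

    ``threshold=None`` selects the Youden-optimal threshold on these scores.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if threshold is None:
        threshold = youden_threshold(s, y)
    rep = confusion_metrics((s >= threshold).astype(int), y, threshold, alpha)
    both = 0 < y.sum() < len(y)
    if both:
        rep.auc, rep.auc_ci = delong_ci(s, y, alpha)
        rep.ap = average_precision(s, y)
        rep.ap_ci = ap_bootstrap_ci(s, y, alpha, reps=ap_reps, seed=seed)
    else:
        rep.flags.append("AUC undefined (single class)")
    return rep


# ---- improvement arithmetic -------------------------------------------------


def relative_improvement(metric_ref: float, metric_new: float) -> float:
    """Relative (ratio) change in percent, one decimal: 100 (new/ref - 1)."""
    if metric_ref <= 0:
        raise DataError("reference metric must be positive")
    return round(100.0 * (metric_new / metric_ref - 1.0), 1)


def absolute_difference_points(metric_ref: float, metric_new: float) -> float:
    """Absolute change in percentage points, one decimal (labeled distinctly
    from the relative convention above)."""
    return round(100.0 * (metric_new - metric_ref), 1)


def error_rate_reduction(err_ref: float, err_new: float) -> float:
    """Relative reduction of an error rate, in percent, one decimal.

    Accepts raw fractions (both in [0, 1]) or pre-rounded percentages (the
    two conventions coexist in practice; the ratio is scale-invariant so either
    works as long as the two arguments share a scale).
    """
    if err_ref <= 0:
        raise DataError("reference error rate must be positive")
    return round(100.0 * (err_ref - err_new) / err_ref, 1)


# ---- baseline association tests ---------------------------------------------


def fisher_exact_doubled(table: np.ndarray) -> float:
    """Fisher exact p for a 2x2 table in the doubled-one-tail dialect:
    twice the smaller one-tailed hypergeometric probability, capped at 1."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError("need a nonnegative 2x2 table")
    a = t[0, 0]
    row1, col1, n = t[0].sum(), t[:, 0].sum(), t.sum()
    if n == 0:
        raise DataError("empty table")
    hg = stats.hypergeom(n, col1, row1)
    lower = hg.cdf(a)
    upper = hg.sf(a - 1)
    return float(min(1.0, 2.0 * min(lower, upper)))


def baseline_association_tests(table) -> tuple[str, float]:
    """Dispatch a contingency-table test the way the baseline tables do:
    Yates-corrected chi-square for 2x2 tables with adequate expected counts,
    the doubled-one-tail Fisher dialect otherwise (2x2), plain chi-square
    for larger tables."""
    t = np.asarray(table, dtype=float)
    if t.size == 0 or t.sum() == 0:
        raise DataError("empty table")
    if (t < 0).any():
        raise DataError("counts must be nonnegative")
    expected = stats.contingency.expected_freq(t)
    if t.shape == (2, 2):
        if (expected >= 5).all():
            chi2, p, _, _ = stats.chi2_contingency(t, correction=True)
            return "chi2_yates", float(p)
        return "fisher_doubled", fisher_exact_doubled(t.astype(int))
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return "chi2", float(p)


def continuous_association_test(group_a, group_b, alpha: float = 0.05) -> tuple[str, float]:
    """Student's t-test when both groups pass Shapiro-Wilk normality at
    ``alpha``, Mann-Whitney U otherwise."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise DataError("need at least 3 observations per group")
    normal = (stats.shapiro(a).pvalue > alpha) and (stats.shapiro(b).pvalue > alpha)
    if normal:
        return "t", float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return "mannwhitney", float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def subgroup_report(scores, labels, grouping, threshold: float,
                    alpha: float = 0.05, seed: int = 0) -> dict[str, MetricsReport]:
    """Per-group metrics (e.g. by molecular subtype or clinical T stage).

    Groups missing a class yield flagged partial reports (thresholded
    metrics only) rather than failures.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    g = np.asarray(grouping)
    if len(g) != len(y):
        raise DataError("grouping must cover all cases")
    out = {}
    for name in sorted(map(str, np.unique(g).tolist())):
        sel = g.astype(str) == name
        out[name] = metrics_report(s[sel], y[sel], threshold=threshold,
                                   alpha=alpha, ap_reps=500, seed=seed)
    return out
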