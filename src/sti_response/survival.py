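"""Survival stratification by model score.

Kaplan-Meier product-limit curves with Greenwood variance, the two-group
log-rank test, and univariate Cox proportional-hazards regression (Efron
tie handling, via lifelines) linking the continuous response score to
recurrence-free and overall survival.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class StrataDefinition:
    rule: str = "median_split"  # | "fixed_threshold"
    score_threshold: float = 0.5

    def split(self, scores: np.ndarray) -> np.ndarray:
        """Boolean high-score group indicator."""
        s = np.asarray(scores, dtype=float)
        if self.rule == "median_split":
            return s >= np.median(s)
        if self.rule == "fixed_threshold":
            if not s.min() <= self.score_threshold <= s.max():
                raise ConfigError("fixed threshold outside the observed score range")
            return s >= self.score_threshold
        raise ConfigError(f"unknown stratification rule {self.rule!r}")


@dataclass
class KmCurve:
    """Left-continuous product-limit estimate: S(t) = value at the largest
    event time <= t; survival[i] applies from times[i] (inclusive) on."""

    times: np.ndarray  # distinct event times
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, alpha: float = 0.05) -> KmCurve:
    """Kaplan-Meier estimator with Greenwood-variance normal intervals."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if np.any(t < 0):
        raise DataError("survival times must be nonnegative")
    if len(t) != len(e):
        raise DataError("times and events must have equal length")
    event_times = np.unique(t[e])
    surv, var_sum = [], []
    s, g = 1.0, 0.0
    at_risk = []
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & e).sum())
        s *= 1.0 - d / n_risk
        if n_risk > d:
            g += d / (n_risk * (n_risk - d))
        at_risk.append(n_risk)
        surv.append(s)
        var_sum.append(g)
    surv = np.asarray(surv)
    se = surv * np.sqrt(np.asarray(var_sum))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return KmCurve(times=event_times, survival=surv,
                   ci_lower=np.clip(surv - z * se, 0.0, 1.0),
                   ci_upper=np.clip(surv + z * se, 0.0, 1.0),
                   at_risk=np.asarray(at_risk))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: observed-vs-expected chi-square, 1 df."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a).astype(bool)
    eb = np.asarray(events_b).astype(bool)
    if len(ta) == 0 or len(tb) == 0:
        raise DataError("both groups must be nonempty")
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e, var = 0.0, 0.0
    for et in event_times:
        n1 = (ta >= et).sum()
        n2 = (tb >= et).sum()
        d1 = ((ta == et) & ea).sum()
        d2 = ((tb == et) & eb).sum()
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxResult:
    hazard_ratio: float
    ci: tuple[float, float]
    p_wald: float
    p_likelihood_ratio: float

    def __post_init__(self):
        if self.hazard_ratio <= 0:
            raise DataError("hazard ratio must be positive")
        if not self.ci[0] <= self.hazard_ratio <= self.ci[1]:
            raise DataError("CI must bracket the hazard ratio")


def cox_univariate(times, events, covariate, standardize: bool = False,
                   alpha: float = 0.05) -> CoxResult:
    """Univariate Cox PH fit (Efron ties).  With ``standardize`` the hazard
    ratio is per standard deviation of the covariate."""
    from lifelines import CoxPHFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    x = np.asarray(covariate, dtype=float)
    if x.std() == 0:
        raise DataError("covariate must vary")
    if standardize:
        x = (x - x.mean()) / x.std()
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event", show_progress=False)
    row = cph.summary.loc["x"]
    lo_col = f"exp(coef) lower {int((1 - alpha) * 100)}%"
    hi_col = f"exp(coef) upper {int((1 - alpha) * 100)}%"
    lr = cph.log_likelihood_ratio_test()
    return CoxResult(
        hazard_ratio=float(row["exp(coef)"]),
        ci=(float(row[lo_col]), float(row[hi_col])),
        p_wald=float(row["p"]),
        p_likelihood_ratio=float(lr.p_value),
    )


def stratified_logrank_report(scores, times, events, strata: StrataDefinition) -> dict:
    """Split by score, compare survival of the high- and low-score groups."""
    s = np.asarray(scores, dtype=float)
    high = strata.split(s)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    chi2, p = logrank_test(t[high], e[high], t[~high], e[~high])
    return {
        "n_high": int(high.sum()), "n_low": int((~high).sum()),
        "chi2": chi2, "p": p,
        "km_high": km_estimate(t[high], e[high]),
        "km_low": km_estimate(t[~high], e[~high]),
    }
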