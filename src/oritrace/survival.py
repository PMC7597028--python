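"""Kaplan-Meier estimation, log-rank comparison, and Cox proportional hazards.

The product-limit estimator and the log-rank statistic are implemented from
their definitions (exact hypergeometric variance at tied event times); the
Cox model delegates to lifelines. Records are plain DataFrames with
``time_days`` and ``event`` columns (event 1 = death/relapse, 0 = censored);
uncertain-group samples are excluded from two-group contrasts upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "restrict_followup",
    "kaplan_meier",
    "logrank_test",
    "median_difference",
    "cox_ph",
    "dichotomize_by_quantile",
]


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("empty survival records")
    for col in ("time_days", "event"):
        if col not in records:
            raise ValueError(f"records must carry a {col!r} column")
    if (records["time_days"] < 0).any():
        raise ValueError("times must be >= 0")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return records


def restrict_followup(records: pd.DataFrame, horizon_days: float) -> pd.DataFrame:
    """Administratively censor every record beyond the horizon.

    Times greater than ``horizon_days`` are truncated to the horizon with
    the event indicator cleared. Idempotent.
    """
    if horizon_days <= 0:
        raise ValueError("horizon must be > 0")
    out = _validate_records(records).copy()
    over = out["time_days"] > horizon_days
    out.loc[over, "time_days"] = horizon_days
    out.loc[over, "event"] = 0
    return out


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``event_times`` are the distinct times with at least one event,
    ascending; ``survival`` the step values just after each;
    ``median`` the smallest time with S(t) <= 0.5, or None if the curve
    never reaches 0.5.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median: Optional[float]
    n: int

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i / n_i)."""
    records = _validate_records(records)
    times = records["time_days"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=int)

    event_times = np.unique(times[events == 1])
    surv, at_risk, d_counts = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_counts.append(d_i)
    surv = np.asarray(surv)
    median = None
    reached = np.where(surv <= 0.5)[0]
    if len(reached):
        median = float(event_times[reached[0]])
    return KMCurve(event_times=event_times, survival=surv,
                   at_risk=np.asarray(at_risk, dtype=int),
                   events=np.asarray(d_counts, dtype=int),
                   median=median, n=len(records))


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test with exact hypergeometric variance at ties.

    Returns (chi2, p) with p from the chi-square distribution on 1 df.
    """
    a = _validate_records(group_a)
    b = _validate_records(group_b)
    ta, ea = a["time_days"].to_numpy(float), a["event"].to_numpy(int)
    tb, eb = b["time_days"].to_numpy(float), b["event"].to_numpy(int)
    all_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if len(all_event_times) == 0:
        raise ValueError("no events in either group")

    u = 0.0
    v = 0.0
    for t in all_event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        n = n1 + n2
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        u += d1 - e1
        if n > 1:
            v += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0, 1.0
    chi2 = u * u / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def median_difference(km_a: KMCurve, km_b: KMCurve) -> Optional[float]:
    """medianA - medianB in days; None when either median is undefined."""
    if km_a.median is None or km_b.median is None:
        return None
    return float(km_a.median - km_b.median)


def dichotomize_by_quantile(values: pd.Series, q: float = 0.5) -> pd.Series:
    """Threshold a continuous covariate at its q-quantile (1 = above)."""
    cut = values.quantile(q)
    return (values > cut).astype(int)


def cox_ph(records: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards fit (Breslow ties) via lifelines.

    Categorical covariates are dummy-coded; continuous covariates should be
    dichotomized beforehand (see :func:`dichotomize_by_quantile`).
    Returns the summary with hazard ratios and 95% confidence intervals.
    """
    from lifelines import CoxPHFitter

    records = _validate_records(records)
    covariates = covariates.loc[records.index]
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant")
    design = pd.get_dummies(covariates, drop_first=True, dtype=float)
    frame = pd.concat([records[["time_days", "event"]], design], axis=1)

    fitter = CoxPHFitter()
    fitter.fit(frame, duration_col="time_days", event_col="event")
    summary = fitter.summary[["coef", "exp(coef)",
                              "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    return summary.rename(columns={
        "exp(coef)": "hazard_ratio",
        "exp(coef) lower 95%": "hr_ci_lower",
        "exp(coef) upper 95%": "hr_ci_upper",
    })
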