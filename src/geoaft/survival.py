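"""Nonparametric survival: Kaplan-Meier curves and k-group log-rank tests.

Deaths from other causes are treated as right-censored, so the event
indicator passed here must mark disease-specific deaths only (see
:func:`event_indicator`).  Estimation is delegated to lifelines
(product-limit estimator; pointwise 95% CI via the exponential-Greenwood
log(-log) transform; k-sample log-rank chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["KMEstimate", "event_indicator", "kaplan_meier", "survival_at", "log_rank"]


def event_indicator(event: pd.Series) -> np.ndarray:
    """1 for disease-specific death, 0 for other-cause death / censoring."""
    return (np.asarray(event, dtype=object) == "pc_death").astype(int)


@dataclass
class KMEstimate:
    """Kaplan-Meier curve with risk-set bookkeeping and log(-log) CI."""

    table: pd.DataFrame  # time, at_risk, events, survival, lower, upper

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy()

    @property
    def survival(self) -> np.ndarray:
        return self.table["survival"].to_numpy()


def kaplan_meier(times, events, alpha: float = 0.05) -> KMEstimate:
    """Product-limit estimator; ties handled by simultaneous events, with
    same-time censorings leaving the risk set after the event."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    ev = kmf.event_table
    ci = kmf.confidence_interval_survival_function_
    table = pd.DataFrame({
        "time": ev.index.to_numpy(dtype=float),
        "at_risk": ev["at_risk"].to_numpy(dtype=int),
        "events": ev["observed"].to_numpy(dtype=int),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        "lower": ci.iloc[:, 0].to_numpy(),
        "upper": ci.iloc[:, 1].to_numpy(),
    })
    return KMEstimate(table)


def survival_at(km: KMEstimate, horizon: float) -> dict:
    """Survival (with CI) at the last observed time <= horizon.

    A horizon past the last observed time returns the terminal value with
    ``truncated=True``; a horizon exactly at an event time includes it.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    t = km.table
    at = t[t["time"] <= horizon]
    if at.empty:
        return {"survival": 1.0, "lower": 1.0, "upper": 1.0, "truncated": False}
    row = at.iloc[-1]
    return {
        "survival": float(row["survival"]),
        "lower": float(row["lower"]),
        "upper": float(row["upper"]),
        "truncated": bool(horizon > t["time"].max()),
    }


def log_rank(groups) -> dict:
    """k-sample log-rank test.

    ``groups`` is a sequence of (times, events) pairs.  Returns the
    chi-square statistic, df = k-1 and the upper-tail p-value.  All groups
    event-free yields statistic 0, p 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if len(t) == 0:
            raise ValueError("each group must be nonempty")
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), g))
    times, events, labels = map(np.concatenate, (times, events, labels))
    df = len(groups) - 1
    if events.sum() == 0:
        return {"statistic": 0.0, "df": df, "p": 1.0}
    res = multivariate_logrank_test(times, labels, events)
    return {
        "statistic": float(res.test_statistic),
        "df": df,
        "p": float(res.p_value),
    }
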