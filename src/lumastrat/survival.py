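"""Kaplan-Meier estimation and log-rank tests.

Thin, validated wrappers around lifelines. The multivariate test is the
(G-1)-df score test over all groups; the pairwise matrix reports raw
(unadjusted) p-values. Ties between events and censorings at the same time
follow the standard convention: events precede censorings, i.e. subjects
censored at an event time are still at risk at that time.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time

from .types import SurvivalTable

__all__ = [
    "KMCurve",
    "LogRankResult",
    "kaplan_meier",
    "logrank_test",
    "pairwise_logrank",
    "rmst",
]


@dataclass
class KMCurve:
    """Product-limit estimate on the event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )

    def at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0-) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def kaplan_meier(tbl: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    if len(tbl) < 1:
        raise ValueError("kaplan_meier needs at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(tbl.time, tbl.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].to_numpy(float)
    # lifelines includes a t=0 anchor row; keep it (S(0)=1 by construction)
    return KMCurve(times, surv, at_risk)


def _stack(groups: list) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    times = np.concatenate([g.time for g in groups])
    events = np.concatenate([g.event for g in groups])
    labels = np.concatenate(
        [np.full(len(g), i, dtype=int) for i, g in enumerate(groups)]
    )
    return times, events, labels


def logrank_test(groups: list) -> LogRankResult:
    """(G-1)-df log-rank chi-squared across all supplied groups."""
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("log-rank test groups must be non-empty")
    times, events, labels = _stack(groups)
    res = multivariate_logrank_test(times, labels, events)
    stat = float(res.test_statistic)
    return LogRankResult(statistic=stat, df=len(groups) - 1, p=float(res.p_value))


def pairwise_logrank(groups: list) -> pd.DataFrame:
    """Symmetric matrix of two-group log-rank p-values; diagonal p = 1.

    ``df.attrs["results"]`` holds the full LogRankResult per (i, j) pair.
    No multiplicity adjustment is applied.
    """
    if len(groups) < 2:
        raise ValueError("pairwise log-rank needs at least two groups")
    k = len(groups)
    pmat = np.ones((k, k))
    results = {}
    for i, j in combinations(range(k), 2):
        res = logrank_test([groups[i], groups[j]])
        pmat[i, j] = pmat[j, i] = res.p
        results[(i, j)] = res
    out = pd.DataFrame(pmat)
    out.attrs["results"] = results
    return out


def rmst(tbl: SurvivalTable, horizon: float) -> float:
    """Restricted mean survival time: area under the KM curve up to
    ``horizon`` months."""
    kmf = KaplanMeierFitter()
    kmf.fit(tbl.time, tbl.event)
    return float(restricted_mean_survival_time(kmf, t=horizon))
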