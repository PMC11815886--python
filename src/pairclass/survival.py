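"""Kaplan–Meier stratification and log-rank testing of predicted clusters.

Curves use the product-limit estimator (deaths processed before censorings
at tied times; censored times never step the curve) and group separation is
tested with the Mantel–Cox log-rank statistic under its chi-square
approximation, either across all groups (k - 1 df) or protective-vs-rest
(1 df). Estimation and testing are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .exceptions import ValidationError
from .types import SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "LogrankResult",
    "SurvivalSummary",
    "km_curve",
    "logrank",
    "summarize_survival",
]


@dataclass
class KMCurve:
    group: str
    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk just before each event time
    median: float              # inf when the curve never falls below 0.5
    n: int


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class SurvivalSummary:
    curves: dict[str, KMCurve]
    all_groups: LogrankResult | None
    protective_vs_rest: LogrankResult | None
    protective: str | None


def km_curve(records: SurvivalTable, group: str) -> KMCurve:
    """Product-limit survival curve for one group of a grouped table."""
    rows = [r for r in records.records if r.group == group]
    if not rows:
        raise ValidationError(f"no records in group {group!r}")
    times = np.array([r.time for r in rows])
    events = np.array([r.event for r in rows])
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    stepped = table[table["observed"] > 0]
    ev_times = stepped.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev_times, "KM_estimate"].to_numpy()
    at_risk = stepped["at_risk"].to_numpy(dtype=int)
    median = float(kmf.median_survival_time_)
    return KMCurve(group, ev_times, surv, at_risk, median, len(rows))


def logrank(
    records: SurvivalTable,
    grouping: dict[str, str] | None = None,
    mode: str = "all_groups",
    protective: str | None = None,
) -> LogrankResult:
    """Mantel–Cox log-rank test over the table's groups.

    ``mode="all_groups"`` tests homogeneity across every group (k - 1 df);
    ``mode="one_vs_rest"`` collapses all non-protective groups and tests the
    protective group against the rest (1 df). ``grouping`` overrides the
    table's own group column when given.
    """
    table = records if grouping is None else records.with_groups(grouping)
    rows = [r for r in table.records if r.group is not None]
    if not rows:
        raise ValidationError("no grouped records")
    groups = np.array([r.group for r in rows])
    times = np.array([r.time for r in rows])
    events = np.array([r.event for r in rows])
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValidationError("log-rank needs at least 2 groups")
    if events.sum() == 0:
        raise ValidationError("log-rank needs at least 1 event")

    if mode == "one_vs_rest":
        if protective is None:
            raise ValidationError("one_vs_rest mode needs a protective group")
        if protective not in uniq:
            raise ValidationError(f"protective group {protective!r} absent")
        mask = groups == protective
        res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
        return LogrankResult(float(res.test_statistic), 1, _clip_p(res.p_value))
    if mode != "all_groups":
        raise ValidationError(f"unknown mode {mode!r}")
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(float(res.test_statistic), len(uniq) - 1, _clip_p(res.p_value))


def _clip_p(p: float) -> float:
    # the chi-square approximation can return exactly 0 at extreme
    # statistics; report the smallest positive float instead
    return float(max(p, np.nextafter(0.0, 1.0)))


def summarize_survival(
    records: SurvivalTable,
    grouping: dict[str, str] | None = None,
    protective: str | None = None,
) -> SurvivalSummary:
    """KM curve and median per group plus the two log-rank tests.

    Groups named by ``protective`` but absent from the data (e.g. a cluster
    to which no sample was assigned) are dropped with a warning; the
    one-vs-rest test is then skipped.
    """
    table = records if grouping is None else records.with_groups(grouping)
    present = sorted({r.group for r in table.records if r.group is not None})
    if not present:
        raise ValidationError("no grouped records to summarize")
    curves = {g: km_curve(table, g) for g in present}
    all_groups = logrank(table) if len(present) >= 2 else None
    pvr = None
    if protective is not None:
        if protective in present:
            pvr = logrank(table, mode="one_vs_rest", protective=protective)
        else:
            logger.warning("protective group %r has no samples; skipping test", protective)
    return SurvivalSummary(curves, all_groups, pvr, protective)
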