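"""Life-history metrics and survival analysis for tagged bee cohorts.

Lifespan is operational: whole days from the tagging date to the date of the
last registration at any hive (own or foreign).  Because monitoring
continued 19 days past the final registration, the default (field-study mode)
treats every bee's last registration as an observed endpoint; the API still
carries an event indicator so right-censored records can be analysed.

Provides the Kaplan-Meier product-limit estimator with Greenwood variance
and the k-sample log-rank test (observed-minus-expected with hypergeometric
variance), plus per-cohort descriptive summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events_io import BeeRecord, Registration, localize

__all__ = [
    "LifeHistoryRecord",
    "KmCurve",
    "life_history_table",
    "cohort_summary",
    "km_estimate",
    "logrank_test",
    "round_percent",
]


@dataclass(frozen=True)
class LifeHistoryRecord:
    tag_id: str
    lifespan_days: int
    first_activity_age_days: int
    n_registrations: int
    registered_once: bool
    event: int = 1  # 1 = endpoint observed, 0 = right-censored
    drift: bool = False  # ever registered at a non-natal hive


def round_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places (as printed in reports)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    q = Decimal(10) ** -decimals
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def life_history_table(
    regs: Sequence[Registration],
    roster: Sequence[BeeRecord],
    utc_offset_hours: float = 2.0,
) -> list[LifeHistoryRecord]:
    """One life-history record per tagged bee with at least one registration.

    Lifespan and first-activity age are calendar-date differences from the
    bee's own tagging date; registrations at foreign hives count.
    """
    by_tag: Mapping[str, BeeRecord] = {b.tag_id: b for b in roster}
    dates: dict[str, list] = {}
    hives: dict[str, set[str]] = {}
    for r in regs:
        if r.tag_id not in by_tag:
            continue
        d = localize(r.timestamp_utc, utc_offset_hours).date()
        dates.setdefault(r.tag_id, []).append(d)
        hives.setdefault(r.tag_id, set()).add(r.hive_id)
    out = []
    for tag, ds in dates.items():
        bee = by_tag[tag]
        lifespan = (max(ds) - bee.tagging_date).days
        first = (min(ds) - bee.tagging_date).days
        out.append(
            LifeHistoryRecord(
                tag_id=tag,
                lifespan_days=lifespan,
                first_activity_age_days=first,
                n_registrations=len(ds),
                registered_once=len(ds) == 1,
                event=1,
                drift=bool(hives[tag] - {bee.natal_hive}),
            )
        )
    out.sort(key=lambda r: r.tag_id)
    return out


def cohort_summary(
    records: Sequence[LifeHistoryRecord],
    roster: Sequence[BeeRecord],
    group_keys: Sequence[str] = ("individual_type",),
) -> pd.DataFrame:
    """Descriptive summary per group: tagging coverage, registration counts,
    lifespan moments and drift.

    The "percent registered" column depends only on presence/absence of
    registrations, never on their multiplicity, and is rounded half-up to
    one decimal as in printed reports.  Drift share is reported against both
    natural denominators (bees registered and bees tagged).
    """
    by_tag = {b.tag_id: b for b in roster}
    rec_rows = []
    for r in records:
        bee = by_tag[r.tag_id]
        rec_rows.append({**r.__dict__, **bee.__dict__})
    recs = pd.DataFrame(rec_rows) if rec_rows else pd.DataFrame(
        columns=["tag_id", "lifespan_days", "first_activity_age_days", "n_registrations",
                 "registered_once", "event", "drift", "individual_type", "subspecies",
                 "natal_hive", "tagging_date", "cohort"]
    )
    ros = pd.DataFrame([b.__dict__ for b in roster])
    out = []
    for key, tagged in ros.groupby(list(group_keys)):
        key = key if isinstance(key, tuple) else (key,)
        sub = recs[
            np.logical_and.reduce(
                [recs[k] == v for k, v in zip(group_keys, key)]
            )
        ] if len(recs) else recs
        n_tagged = len(tagged)
        n_reg = len(sub)
        row = dict(zip(group_keys, key))
        row.update(
            n_tagged=n_tagged,
            n_registered=n_reg,
            percent_registered=round_percent(n_reg, n_tagged) if n_tagged else np.nan,
            n_registered_once=int(sub["registered_once"].sum()) if n_reg else 0,
            median_n_registrations=float(sub["n_registrations"].median()) if n_reg else np.nan,
            iqr_n_registrations=float(
                sub["n_registrations"].quantile(0.75) - sub["n_registrations"].quantile(0.25)
            ) if n_reg else np.nan,
            mean_lifespan=float(sub["lifespan_days"].mean()) if n_reg else np.nan,
            sd_lifespan=float(sub["lifespan_days"].std(ddof=1)) if n_reg > 1 else np.nan,
            se_lifespan=float(sub["lifespan_days"].std(ddof=1) / np.sqrt(n_reg))
            if n_reg > 1 else np.nan,
            max_lifespan=int(sub["lifespan_days"].max()) if n_reg else 0,
            n_drifted=int(sub["drift"].sum()) if n_reg else 0,
            percent_drifted_of_registered=round_percent(int(sub["drift"].sum()), n_reg)
            if n_reg else np.nan,
            percent_drifted_of_tagged=round_percent(int(sub["drift"].sum()), n_tagged)
            if n_tagged else np.nan,
        )
        out.append(row)
    return pd.DataFrame(out)


@dataclass
class KmCurve:
    """Kaplan-Meier product-limit curve.

    ``t`` are the distinct event times, ``n_risk`` the numbers at risk just
    before each, ``d`` the event counts, ``survival`` S(t) and ``var`` the
    Greenwood variance estimate of S(t).
    """

    t: np.ndarray
    n_risk: np.ndarray
    d: np.ndarray
    survival: np.ndarray
    var: np.ndarray

    def survival_at(self, times: np.ndarray | float) -> np.ndarray:
        """Step-function evaluation S(time) (right-continuous)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.t, times, side="right") - 1
        s = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return s

    @property
    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.t[below][0]) if below.any() else float("nan")

    @property
    def mean(self) -> float:
        """Restricted mean survival time up to the largest observed time."""
        s_prev = np.concatenate([[1.0], self.survival[:-1]])
        t_prev = np.concatenate([[0.0], self.t[:-1]])
        return float(np.sum(s_prev * (self.t - t_prev)))


def km_estimate(records: Sequence[tuple[float, int]]) -> KmCurve:
    """Product-limit survival estimate from ``(time, event)`` pairs.

    Ties are handled by simultaneous events; censored times reduce the risk
    set after the event times they coincide with.  With no censoring the
    estimate equals the empirical survival function.
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    times = np.asarray([t for t, _ in records], dtype=float)
    events = np.asarray([e for _, e in records], dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival time")
    event_times = np.unique(times[events == 1])
    n = len(times)
    t_out, n_out, d_out, s_out, v_out = [], [], [], [], []
    s = 1.0
    greenwood = 0.0
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            greenwood += d / (at_risk * (at_risk - d))
        t_out.append(t)
        n_out.append(at_risk)
        d_out.append(d)
        s_out.append(s)
        v_out.append(s * s * greenwood)
    return KmCurve(
        t=np.asarray(t_out),
        n_risk=np.asarray(n_out),
        d=np.asarray(d_out),
        survival=np.asarray(s_out),
        var=np.asarray(v_out),
    )


def logrank_test(groups: Sequence[Sequence[tuple[float, int]]]) -> tuple[float, int, float]:
    """k-sample log-rank test; returns ``(chi2, df, p)``.

    The statistic is the quadratic form of the summed observed-minus-expected
    event counts with the hypergeometric covariance, evaluated on the first
    k-1 groups; identical groups give chi2 = 0.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    times = np.concatenate([[t for t, _ in g] for g in groups])
    events = np.concatenate([[e for _, e in g] for g in groups]).astype(int)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    event_times = np.unique(times[events == 1])
    oe = np.zeros(k - 1)
    cov = np.zeros((k - 1, k - 1))
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        n_g = np.array([int((at_risk & (labels == g)).sum()) for g in range(k)], dtype=float)
        d_g = np.array(
            [int(((times == t) & (events == 1) & (labels == g)).sum()) for g in range(k)],
            dtype=float,
        )
        e_g = d_t * n_g / n_t
        oe += (d_g - e_g)[: k - 1]
        if n_t > 1:
            frac = d_t * (n_t - d_t) / (n_t - 1) / n_t**2
            v = frac * (np.diag(n_g[: k - 1] * n_t) - np.outer(n_g[: k - 1], n_g[: k - 1]))
            cov += v
    if not np.any(cov):
        return 0.0, k - 1, 1.0
    chi2 = float(oe @ np.linalg.solve(cov, oe))
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
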