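"""Nonparametric tests and unbalanced factorial ANOVA, implemented from first
principles.

The conventions follow the R ecosystem the original field analyses were run
in: the Mann-Whitney ``W`` is the rank-sum of the first sample minus
``n1(n1+1)/2`` (identical to the U count of (x, y) pairs with x > y, halved
for ties), Spearman's rho is the product-moment correlation of midranks, and
the factorial ANOVA uses Type-II sums of squares (each main effect tested
after the other, the interaction after both) so that unbalanced designs are
handled in the standard way.  Each statistic has a brute-force oracle in the
test suite; scipy/statsmodels serve only as independent cross-checks there.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "RankTestResult",
    "Anova2Result",
    "mann_whitney",
    "spearman_rho",
    "daily_weather_correlations",
    "type2_anova",
    "tukey_hsd",
]


@dataclass(frozen=True)
class RankTestResult:
    W: float  # rank-sum of sample 1 minus n1(n1+1)/2
    U: float  # Mann-Whitney count; equals W under this convention
    p_value: float
    method: str  # "exact" | "normal-approx-with-tie-correction"


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Arrangement counts by U value for tie-free samples under the null.

    Uses the classic recursion N(u; a, b) = N(u-b; a-1, b) + N(u; a, b-1)
    (condition on whether the largest pooled value belongs to sample 1,
    in which case it beats all b values of sample 2).
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(a: int, b: int) -> tuple[int, ...]:
        if a == 0 or b == 0:
            return (1,)
        prev_a = f(a - 1, b)
        prev_b = f(a, b - 1)
        out = []
        for u in range(a * b + 1):
            v = 0
            if 0 <= u - b <= (a - 1) * b:
                v += prev_a[u - b]
            if u <= a * (b - 1):
                v += prev_b[u]
            out.append(v)
        return tuple(out)

    return np.asarray(f(n1, n2), dtype=float)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney rank test.

    Exact p by null enumeration when ``n1 + n2 <= 14`` and the pooled sample
    is tie-free, otherwise the normal approximation with continuity and tie
    correction.  Midranks are used for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= 14 and not has_ties:
        counts = _u_null_counts(n1, n2)
        total = comb(n1 + n2, n1)
        u = int(round(w))
        lower = counts[: u + 1].sum() / total
        upper = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return RankTestResult(W=w, U=w, p_value=float(p), method="exact")
    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankTestResult(W=w, U=w, p_value=1.0,
                              method="normal-approx-with-tie-correction")
    z = (w - mean - 0.5 * np.sign(w - mean)) / sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RankTestResult(W=w, U=w, p_value=min(1.0, p),
                          method="normal-approx-with-tie-correction")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Returns NaN (not 0) when either series is constant — a constant series
    carries no ordering information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / sqrt((rx @ rx) * (ry @ ry)))


def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p for Spearman's rho via the t approximation."""
    if np.isnan(rho) or n < 3:
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * sqrt((n - 2) / (1 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def daily_weather_correlations(
    hourly: pd.DataFrame,
    variables: Sequence[str] = ("temperature", "light", "wind", "rain_sum"),
    min_hours: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-day Spearman correlations between hourly counts and weather.

    For every calendar day with at least ``min_hours`` valid hours, the
    hourly registration counts (pooled over the hives present in ``hourly``)
    are correlated against each weather variable; days on which a variable
    is constant (e.g. rain-free days) yield NA for that variable.  The
    summary gives the median and IQR of the daily correlations — the medians
    are the headline "weather effect" numbers.
    """
    pooled = (
        hourly.dropna(subset=["count"])
        .groupby(["date", "hour"], as_index=False)
        .agg(count=("count", "sum"), **{v: (v, "mean") for v in variables})
    )
    rows = []
    for day, sub in pooled.groupby("date"):
        sub = sub.dropna(subset=list(variables))
        if len(sub) < min_hours:
            continue
        row = {"date": day}
        for v in variables:
            row[v] = spearman_rho(sub["count"].to_numpy(), sub[v].to_numpy())
        rows.append(row)
    per_day = pd.DataFrame(rows, columns=["date", *variables])
    summary_rows = []
    for v in variables:
        vals = per_day[v].dropna() if len(per_day) else pd.Series(dtype=float)
        if len(vals) == 0:
            continue
        summary_rows.append(
            {
                "variable": v,
                "n_days": int(len(vals)),
                "median_rho": float(vals.median()),
                "iqr_rho": float(vals.quantile(0.75) - vals.quantile(0.25)),
            }
        )
    return per_day, pd.DataFrame(summary_rows, columns=["variable", "n_days", "median_rho", "iqr_rho"])


# ---------------------------------------------------------------------------
# Type-II factorial ANOVA


@dataclass
class Anova2Result:
    """Type-II two-way ANOVA with a Tukey HSD table on the cell means."""

    table: pd.DataFrame  # terms A, B, A:B, Residual with ss, df, F, p
    tukey: pd.DataFrame = field(default_factory=pd.DataFrame)
    transform: str = "none"


def _dummies(factor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = np.unique(factor)
    cols = np.column_stack([(factor == lv).astype(float) for lv in levels[1:]])
    if cols.size == 0:
        cols = np.empty((len(factor), 0))
    return cols, levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(np.sum((y - y.mean()) ** 2))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def type2_anova(
    response: Sequence[float],
    A: Sequence,
    B: Sequence,
    transform: str = "none",
) -> Anova2Result:
    """Two-way factorial ANOVA with Type-II sums of squares.

    Each sum of squares is a difference of residual sums of squares between
    nested least-squares fits: SS_A = RSS(B) - RSS(A+B), SS_B = RSS(A) -
    RSS(A+B), SS_AB = RSS(A+B) - RSS(A+B+A:B).  ``transform`` may be
    ``"log1p"`` for count responses (log(y+1), which keeps zero counts in
    the analysis) or ``"log"`` for strictly positive responses.
    """
    y = np.asarray(response, dtype=float)
    if transform == "log1p":
        y = np.log1p(y)
    elif transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive response")
        y = np.log(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    A = np.asarray(A)
    B = np.asarray(B)
    n = len(y)
    XA, levels_a = _dummies(A)
    XB, levels_b = _dummies(B)
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    ones = np.ones((n, 1))
    XAB = np.column_stack([XA[:, i] * XB[:, j]
                           for i in range(XA.shape[1]) for j in range(XB.shape[1])])
    X_full = np.column_stack([ones, XA, XB, XAB])
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        raise ValueError("rank-deficient design: A:B cells aliased (empty cells)")

    rss_b = _rss(np.column_stack([ones, XB]), y)
    rss_a = _rss(np.column_stack([ones, XA]), y)
    rss_ab = _rss(np.column_stack([ones, XA, XB]), y)
    rss_full = _rss(X_full, y)

    ss = {
        "A": rss_b - rss_ab,
        "B": rss_a - rss_ab,
        "A:B": rss_ab - rss_full,
        "Residual": rss_full,
    }
    df = {
        "A": len(levels_a) - 1,
        "B": len(levels_b) - 1,
        "A:B": (len(levels_a) - 1) * (len(levels_b) - 1),
        "Residual": n - X_full.shape[1],
    }
    if df["Residual"] <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = ss["Residual"] / df["Residual"]
    rows = []
    for term in ("A", "B", "A:B", "Residual"):
        if term == "Residual":
            rows.append({"term": term, "ss": ss[term], "df": df[term],
                         "F": np.nan, "p": np.nan})
        else:
            f = ss[term] / df[term] / mse
            rows.append({"term": term, "ss": ss[term], "df": df[term], "F": f,
                         "p": float(stats.f.sf(f, df[term], df["Residual"]))})
    cells = pd.DataFrame({"y": y, "A": A, "B": B})
    cells["cell"] = cells["A"].astype(str) + ":" + cells["B"].astype(str)
    tukey = tukey_hsd(cells["y"].to_numpy(), cells["cell"].to_numpy(),
                      mse=mse, df_resid=df["Residual"])
    return Anova2Result(table=pd.DataFrame(rows), tukey=tukey, transform=transform)


def tukey_hsd(
    y: np.ndarray,
    group: np.ndarray,
    mse: float | None = None,
    df_resid: int | None = None,
) -> pd.DataFrame:
    """Tukey(-Kramer) honestly-significant-difference pairwise table.

    Adjusted p-values come from the Studentized range distribution on the
    group (cell) means; with unequal cell sizes the Tukey-Kramer standard
    error is used.  ``mse``/``df_resid`` default to the one-way within-group
    values but can be supplied from a surrounding model.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    k = len(levels)
    means = {lv: y[group == lv].mean() for lv in levels}
    ns = {lv: int((group == lv).sum()) for lv in levels}
    if mse is None or df_resid is None:
        df_resid = len(y) - k
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom for Tukey HSD")
        mse = sum(float(np.sum((y[group == lv] - means[lv]) ** 2)) for lv in levels) / df_resid
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = means[b] - means[a]
        se = sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
        else:
            q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append({"group1": a, "group2": b, "diff": diff, "se": se,
                     "q": q, "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)
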