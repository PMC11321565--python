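"""Rank tests, Spearman correlations and Type-II factorial ANOVA against
brute-force oracles and the scipy/statsmodels reference implementations."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hivetrax.classic_stats import (
    daily_weather_correlations,
    mann_whitney,
    spearman_rho,
    tukey_hsd,
    type2_anova,
)


# --------------------------------------------------------------- Mann-Whitney


def test_w_extremes():
    assert mann_whitney([1, 2], [3, 4]).W == 0
    assert mann_whitney([3, 4], [1, 2]).W == 4  # n1*n2


def _enumeration_p(x, y):
    """Exact two-sided p by enumerating every assignment of the pooled ranks."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    ws = []
    for idx in itertools.combinations(range(n), n1):
        ws.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs)
    upper = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(lower, upper))


def test_exact_p_equals_enumeration(rng):
    for n1 in range(1, 6):
        for n2 in range(1, 6):
            for _ in range(3):
                x = rng.permutation(100)[: n1 + n2]
                res = mann_whitney(x[:n1], x[n1:])
                assert res.method == "exact"
                assert res.p_value == pytest.approx(
                    _enumeration_p(x[:n1], x[n1:]), abs=1e-12
                )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 10**6), min_size=1, max_size=25, unique=True),
)
def test_w_antisymmetry(pool):
    if len(pool) < 2:
        return
    n1 = len(pool) // 2
    x, y = pool[:n1], pool[n1:]
    assert mann_whitney(x, y).W + mann_whitney(y, x).W == len(x) * len(y)


def test_exact_and_approx_agree_for_moderate_n(rng):
    x = rng.normal(0, 1, size=20)
    y = rng.normal(0.3, 1, size=22)
    res = mann_whitney(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.U == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_tie_correction_matches_scipy(rng):
    x = rng.integers(0, 5, size=30)
    y = rng.integers(0, 5, size=28)
    res = mann_whitney(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# ------------------------------------------------------------------- Spearman


def test_spearman_monotone_extremes():
    x = [1, 2, 3, 4, 5]
    assert spearman_rho(x, [2, 4, 6, 8, 10]) == pytest.approx(1.0)
    assert spearman_rho(x, [5, 4, 3, 2, 1]) == pytest.approx(-1.0)


def test_spearman_constant_series_is_nan():
    assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


def test_spearman_ties_equal_pearson_on_midranks(rng):
    x = rng.integers(0, 6, size=40).astype(float)
    y = rng.integers(0, 6, size=40).astype(float)
    rho = spearman_rho(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(oracle, abs=1e-12)
    assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(-100, 100), min_size=4, max_size=30, unique=True),
       st.integers(0, 3))
def test_spearman_invariant_under_monotone_transform(x, which):
    rng = np.random.default_rng(7)
    y = list(rng.permutation(len(x)).astype(float))
    transforms = [np.arctan, lambda v: v**3, lambda v: 2 * v + 1,
                  lambda v: np.exp(v / 50.0)]
    f = transforms[which]
    x = np.asarray(x, dtype=float)
    assert spearman_rho(x, y) == pytest.approx(spearman_rho(f(x), y), abs=1e-9)


# ------------------------------------------------- per-day weather correlations


def _hourly_frame(days):
    rows = []
    for d, (counts, temps, rains) in days.items():
        for h, (c, t, r) in enumerate(zip(counts, temps, rains)):
            rows.append({"date": d, "hour": h, "count": float(c),
                         "temperature": t, "light": 50.0 + h, "wind": 5.0,
                         "rain_sum": r})
    return pd.DataFrame(rows)


def test_counts_tracking_temperature_give_rho_one():
    temps = np.linspace(5, 20, 24)
    days = {"2022-06-01": (np.argsort(np.argsort(temps)) + 1.0, temps, np.zeros(24))}
    per_day, summary = daily_weather_correlations(_hourly_frame(days))
    assert per_day["temperature"].item() == pytest.approx(1.0)
    assert np.isnan(per_day["rain_sum"].item())  # rain-free day: constant series
    assert summary.set_index("variable").loc["temperature", "median_rho"] == pytest.approx(1.0)


def test_median_rho_matches_per_day_oracle(rng):
    days = {}
    for i in range(10):
        temps = rng.normal(15, 4, size=24)
        counts = np.exp(0.2 * temps) + rng.normal(0, 0.5, size=24)
        days[f"2022-06-{i+1:02d}"] = (counts, temps, rng.exponential(0.1, 24))
    frame = _hourly_frame(days)
    per_day, summary = daily_weather_correlations(frame)
    oracle = []
    for _, sub in frame.groupby("date"):
        oracle.append(stats.spearmanr(sub["count"], sub["temperature"]).statistic)
    med = summary.set_index("variable").loc["temperature", "median_rho"]
    assert med == pytest.approx(np.median(oracle), abs=1e-12)


# ------------------------------------------------------------- Type-II ANOVA


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(((y - X @ beta) ** 2).sum())


def _oracle_type2(y, A, B):
    """Independent RSS-comparison oracle using patsy-free dummy encoding."""
    y = np.asarray(y, float)
    da = pd.get_dummies(pd.Series(A), drop_first=True).to_numpy(float)
    db = pd.get_dummies(pd.Series(B), drop_first=True).to_numpy(float)
    ones = np.ones((len(y), 1))
    dab = np.column_stack([da[:, i] * db[:, j]
                           for i in range(da.shape[1]) for j in range(db.shape[1])])
    rss_b = _rss(np.hstack([ones, db]), y)
    rss_a = _rss(np.hstack([ones, da]), y)
    rss_ab = _rss(np.hstack([ones, da, db]), y)
    rss_full = _rss(np.hstack([ones, da, db, dab]), y)
    return {"A": rss_b - rss_ab, "B": rss_a - rss_ab, "A:B": rss_ab - rss_full,
            "Residual": rss_full}


def test_balanced_design_type2_equals_sequential(rng):
    A = np.repeat(["a1", "a2"], 8)
    B = np.tile(np.repeat(["b1", "b2"], 4), 2)
    y = rng.normal(0, 1, size=16) + (A == "a2") * 0.5 + (B == "b2") * 1.0
    res = type2_anova(y, A, B)
    tab = res.table.set_index("term")
    # sequential SS from either order equal Type-II SS in a balanced design
    da = pd.get_dummies(pd.Series(A), drop_first=True).to_numpy(float)
    db = pd.get_dummies(pd.Series(B), drop_first=True).to_numpy(float)
    ones = np.ones((16, 1))
    seq_a_first = _rss(ones, y) - _rss(np.hstack([ones, da]), y)
    seq_a_second = _rss(np.hstack([ones, db]), y) - _rss(np.hstack([ones, db, da]), y)
    assert seq_a_first == pytest.approx(seq_a_second, abs=1e-9)
    assert tab.loc["A", "ss"] == pytest.approx(seq_a_first, abs=1e-9)


def test_unbalanced_ss_match_rss_oracle(rng):
    A = np.array(["a1"] * 5 + ["a2"] * 5)
    B = np.array(["b1"] * 3 + ["b2"] * 2 + ["b1"] * 2 + ["b2"] * 3)
    y = rng.normal(0, 1, size=10)
    res = type2_anova(y, A, B)
    tab = res.table.set_index("term")
    oracle = _oracle_type2(y, A, B)
    for term, ss in oracle.items():
        assert tab.loc[term, "ss"] == pytest.approx(ss, abs=1e-10)


def test_anova_matches_statsmodels(rng):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    n = 60
    df = pd.DataFrame({
        "A": rng.choice(["x", "y"], size=n, p=[0.35, 0.65]),
        "B": rng.choice(["m1", "m2", "m3", "m4"], size=n),
    })
    df["y"] = rng.normal(0, 1, n) + (df["A"] == "y") * 0.8
    res = type2_anova(df["y"], df["A"], df["B"])
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    ref = sm.stats.anova_lm(model, typ=2)
    tab = res.table.set_index("term")
    assert tab.loc["A", "ss"] == pytest.approx(ref.loc["C(A)", "sum_sq"], rel=1e-8)
    assert tab.loc["B", "ss"] == pytest.approx(ref.loc["C(B)", "sum_sq"], rel=1e-8)
    assert tab.loc["A:B", "ss"] == pytest.approx(ref.loc["C(A):C(B)", "sum_sq"], rel=1e-8)
    assert tab.loc["A", "p"] == pytest.approx(ref.loc["C(A)", "PR(>F)"], rel=1e-6)


def test_empty_cell_is_reported(rng):
    A = np.array(["a1"] * 4 + ["a2"] * 4)
    B = np.array(["b1", "b1", "b2", "b2", "b1", "b1", "b1", "b1"])  # a2:b2 empty
    with pytest.raises(ValueError, match="aliased|rank"):
        type2_anova(rng.normal(size=8), A, B)


def test_log_transform_requires_positive():
    with pytest.raises(ValueError):
        type2_anova([0.0, 1, 2, 3], ["a", "a", "b", "b"], ["x", "y", "x", "y"],
                    transform="log")


def test_tukey_identical_groups_p_near_one(rng):
    base = rng.normal(0, 1, size=12)
    y = np.concatenate([base, base])
    g = np.array(["g1"] * 12 + ["g2"] * 12)
    tab = tukey_hsd(y, g)
    assert tab["p_adj"].item() > 0.99


def test_tukey_matches_statsmodels(rng):
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    y = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 12),
                        rng.normal(2, 1, 18)])
    g = np.array(["a"] * 15 + ["b"] * 12 + ["c"] * 18)
    ours = tukey_hsd(y, g).set_index(["group1", "group2"])
    ref = pairwise_tukeyhsd(y, g)
    for (g1, g2), diff, p in zip(itertools.combinations(["a", "b", "c"], 2),
                                 ref.meandiffs, ref.pvalues):
        assert ours.loc[(g1, g2), "diff"] == pytest.approx(diff)
        assert ours.loc[(g1, g2), "p_adj"] == pytest.approx(p, abs=1e-6)
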