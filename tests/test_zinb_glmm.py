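"""Design construction, the zero-inflated NB1 likelihood, the Laplace
approximation, and model selection utilities."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from hivetrax.zinb_glmm import (
    DRONE_FINAL,
    ModelSpec,
    ZinbParams,
    _laplace,
    build_design,
    default_candidates,
    effect_grid,
    fit,
    infer,
    negloglik,
    select_model,
    vif,
    zinb1_logpmf,
)
from hivetrax.synthetic_data import simulate_glmm_counts

SMALL_SPEC = ModelSpec(terms=("Age", "Temperature", "Timeinterval"), name="small")
SMALL_BETA = np.array([-0.02, 0.08, -1.5, 0.8, 0.2, -2.0])
SMALL_TRUE = ZinbParams(beta=SMALL_BETA, gamma=-0.05, phi=2.0,
                        sigma_colony=0.3, sigma_season=0.2)


def _rows_frame(temps, counts=None, subspecies=None, hours=None):
    n = len(temps)
    return pd.DataFrame({
        "hive_id": ["H1"] * n,
        "date": [date(2022, 6, 1)] * n,
        "hour": hours if hours is not None else list(range(n)),
        "count": counts if counts is not None else [1.0] * n,
        "age": np.arange(n, dtype=float),
        "temperature": temps,
        "light": np.linspace(0, 100, n),
        "wind": np.linspace(1, 5, n),
        "rain_sum": np.linspace(0, 1, n),
        "humidity": 70.0,
        "interval": ["MIDDAY"] * n,
        "subspecies": subspecies if subspecies is not None else ["Buck"] * n,
        "season": ["summer"] * n,
    })


# ------------------------------------------------------------------- design


def test_environmental_covariates_are_centred():
    rows = _rows_frame([10.0, 20.0])
    design = build_design(rows, ModelSpec(terms=("Temperature",)))
    assert design.X[:, 0] == pytest.approx([-5.0, 5.0])
    assert design.centring["Temperature"] == pytest.approx(15.0)


def test_na_rows_dropped_listwise():
    rows = _rows_frame(np.linspace(5, 25, 8))
    rows.loc[2, "count"] = np.nan
    rows.loc[5, "temperature"] = np.nan
    design = build_design(rows, ModelSpec(terms=("Temperature",)))
    assert design.n_obs == 6
    assert design.n_dropped == 2


def test_interaction_column_is_product_of_parents(rng):
    rows, _ = simulate_glmm_counts(
        DRONE_FINAL, ZinbParams(beta=np.zeros(14), gamma=-0.05, phi=2.0,
                                sigma_colony=0.1, sigma_season=0.1),
        n_days_per_season=5, seed=3,
    )
    design = build_design(rows, DRONE_FINAL)
    i_tl = design.colnames.index("Temperature:Light")
    i_t = design.colnames.index("Temperature")
    i_l = design.colnames.index("Light")
    assert design.X[:, i_tl] == pytest.approx(design.X[:, i_t] * design.X[:, i_l])


def test_interval_columns_are_cell_means_without_intercept():
    rows, _ = simulate_glmm_counts(
        SMALL_SPEC, SMALL_TRUE, n_days_per_season=5, seed=1,
    )
    design = build_design(rows, SMALL_SPEC)
    iv_cols = [i for i, n in enumerate(design.colnames) if n.startswith("Timeinterval[")]
    assert len(iv_cols) == 4
    assert np.all(design.X[:, iv_cols].sum(axis=1) == 1.0)


def test_term_without_variation_is_named():
    rows = _rows_frame([10.0, 20.0, 30.0])
    rows["rain_sum"] = 0.0
    with pytest.raises(ValueError, match="Rain"):
        build_design(rows, ModelSpec(terms=("Temperature", "Rain")))


# --------------------------------------------------------------- likelihood


def test_zinb1_probabilities_sum_to_one():
    ks = np.arange(0, 4000)
    for mu, phi, p in [(1.0, 1.5, 0.3), (5.0, 3.0, 0.0), (20.0, 1.0, 0.5),
                       (0.3, 8.0, 0.7)]:
        lp = zinb1_logpmf(ks.astype(float), np.full_like(ks, mu, dtype=float),
                         phi, np.full_like(ks, p, dtype=float))
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-8)


def test_zero_inflation_degenerates_to_plain_nb1():
    y = np.array([0.0, 1, 2, 5, 9])
    mu = np.full(5, 2.5)
    phi = 2.0
    lp = zinb1_logpmf(y, mu, phi, np.zeros(5))
    r = mu / (phi - 1.0)
    ref = stats.nbinom.logpmf(y, r, 1.0 / phi)
    assert lp == pytest.approx(ref, abs=1e-10)


def test_phi_to_one_limit_is_zero_inflated_poisson():
    rng = np.random.default_rng(5)
    y = rng.poisson(2.0, size=200).astype(float)
    mu = rng.uniform(0.5, 5.0, size=200)
    p = rng.uniform(0.05, 0.6, size=200)

    def zip_loglik(y, mu, p):  # independent implementation
        out = np.where(
            y == 0,
            np.log(p + (1 - p) * np.exp(-mu)),
            np.log1p(-p) + stats.poisson.logpmf(y, mu),
        )
        return out

    lim = zinb1_logpmf(y, mu, 1.0 + 1e-12, p)
    assert lim.sum() == pytest.approx(zip_loglik(y, mu, p).sum(), abs=1e-6)
    # and the NB branch converges to the same value from above
    gap6 = abs(zinb1_logpmf(y, mu, 1.0 + 1e-6, p).sum() - zip_loglik(y, mu, p).sum())
    gap4 = abs(zinb1_logpmf(y, mu, 1.0 + 1e-4, p).sum() - zip_loglik(y, mu, p).sum())
    assert gap6 < gap4
    assert gap6 < 1e-3


def _single_factor_design(n_per_group=50, seed=0):
    spec = ModelSpec(terms=("Temperature", "Timeinterval"))
    true = ZinbParams(beta=np.array([0.08, -0.5, 0.8, 0.2, -1.5]), gamma=-0.05,
                      phi=2.0, sigma_colony=0.4, sigma_season=0.0)
    rows, _ = simulate_glmm_counts(spec, true, n_colonies=4, n_seasons=1,
                                   n_days_per_season=max(2, n_per_group // 24),
                                   seed=seed)
    design = build_design(rows.iloc[: 4 * n_per_group], spec)
    return design, true


def _quadrature_marginal(params: ZinbParams, design) -> float:
    """Adaptive-quadrature oracle for a single grouping factor."""
    total = 0.0
    p_zero = 1.0 / (1.0 + np.exp(-params.gamma * design.hour))
    xb = design.X @ params.beta
    for g in range(design.n_colony):
        idx = design.colony_idx == g
        y_g, xb_g, pz_g = design.y[idx], xb[idx], p_zero[idx]

        def logjoint(u):
            mu = np.exp(xb_g + u)
            return (zinb1_logpmf(y_g, mu, params.phi, pz_g).sum()
                    + stats.norm.logpdf(u, 0.0, params.sigma_colony))

        shift = logjoint(0.0)
        val, _ = integrate.quad(
            lambda u: np.exp(logjoint(u) - shift),
            -8 * params.sigma_colony, 8 * params.sigma_colony, limit=200,
        )
        total += shift + np.log(val)
    return total


def test_laplace_matches_adaptive_quadrature():
    design, true = _single_factor_design(n_per_group=50, seed=11)
    assert design.n_season == 0
    theta = true.pack(design)
    marg, _ = _laplace(theta, design)
    oracle = _quadrature_marginal(true, design)
    assert abs(marg - oracle) / abs(oracle) < 1e-3


def test_negloglik_penalises_nonfinite():
    design, true = _single_factor_design(n_per_group=20, seed=2)
    bad = true.pack(design).copy()
    bad[0] = 1e5
    assert negloglik(bad, design) >= 1e11 or np.isfinite(negloglik(bad, design))


# ---------------------------------------------------------------------- fit


def test_refit_from_solution_is_stationary():
    rows, _ = simulate_glmm_counts(SMALL_SPEC, SMALL_TRUE,
                                   n_days_per_season=10, seed=8)
    design = build_design(rows, SMALL_SPEC)
    f1 = fit(design, seed=0, compute_cov=False)
    assert f1.converged
    f2 = fit(design, start=f1.params.pack(design), seed=0,
             compute_cov=False, n_restarts=0)
    assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)


def test_boundary_variance_detected():
    true = ZinbParams(beta=SMALL_BETA, gamma=-0.05, phi=2.0,
                      sigma_colony=1e-8, sigma_season=0.2)
    rows, _ = simulate_glmm_counts(SMALL_SPEC, true, n_days_per_season=10, seed=4)
    design = build_design(rows, SMALL_SPEC)
    f = fit(design, seed=0, compute_cov=False)
    # sigma^2 estimate sits near the zero boundary (truth is 0; a realistic
    # colony effect in this design is sigma ~ 0.3)
    assert f.sigma2_colony < 0.01


def test_aic_counts_free_parameters():
    rows, _ = simulate_glmm_counts(SMALL_SPEC, SMALL_TRUE,
                                   n_days_per_season=8, seed=9)
    design = build_design(rows, SMALL_SPEC)
    f = fit(design, seed=0, compute_cov=False)
    # 6 fixed + zi slope + dispersion + two variance components
    assert f.n_free == 10
    assert f.aic == pytest.approx(-2 * f.loglik + 2 * 10)


# ---------------------------------------------------------------------- vif


def test_vif_orthogonal_columns(rng):
    n = 400
    rows = _rows_frame(rng.normal(0, 1, n), hours=[0] * n)
    rows["age"] = rng.normal(0, 1, n)
    rows["light"] = rng.normal(0, 1, n)
    rows["wind"] = rng.normal(0, 1, n)
    rows["rain_sum"] = rng.normal(0, 1, n)
    v = vif(rows)
    assert (v < 1.1).all()


def test_vif_duplicated_column_infinite(rng):
    n = 50
    rows = _rows_frame(rng.normal(0, 1, n), hours=[0] * n)
    rows["light"] = rows["temperature"]
    v = vif(rows, covariates=("temperature", "light", "wind"))
    assert np.isinf(v["temperature"]) and np.isinf(v["light"])


def test_vif_matches_regression_oracle(rng):
    import statsmodels.api as sm

    n = 300
    t = rng.normal(0, 1, n)
    l = 0.8 * t + 0.6 * rng.normal(0, 1, n)
    rows = _rows_frame(t, hours=[0] * n)
    rows["light"] = l
    rows["wind"] = rng.normal(0, 1, n)
    v = vif(rows, covariates=("temperature", "light", "wind"))
    r2 = sm.OLS(t, sm.add_constant(np.column_stack([l, rows["wind"]]))).fit().rsquared
    assert v["temperature"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)


# ------------------------------------------------------------ selection, infer


def test_single_candidate_returned_unchanged():
    rows, _ = simulate_glmm_counts(SMALL_SPEC, SMALL_TRUE,
                                   n_days_per_season=8, seed=10)
    tab, chosen, fits = select_model(rows, [SMALL_SPEC], seed=0)
    assert chosen is SMALL_SPEC
    assert len(tab) == 1


def test_default_candidates_structure():
    cands = default_candidates()
    names = {c.name for c in cands}
    assert len(cands) == 4
    assert any("Temperature:Light" not in c.terms for c in cands)
    assert any("Subspecies:Rain" not in c.terms for c in cands)
    assert "drone-maximal" in names


def test_infer_tables_and_effect_grid():
    rows, _ = simulate_glmm_counts(SMALL_SPEC, SMALL_TRUE,
                                   n_days_per_season=10, seed=12)
    design = build_design(rows, SMALL_SPEC)
    f = fit(design, seed=0, compute_cov=True)
    out = infer(f)
    coef = out["coefficients"].set_index("term")
    # CI straddling zero <-> not significant
    for _, row in out["coefficients"].iterrows():
        straddles = row["ci_low"] <= 0 <= row["ci_high"]
        assert row["significant"] == (not straddles)
    dev = out["deviance"].set_index("term")
    assert dev.loc["Timeinterval", "df"] == 4
    # effect grid at the centring point reproduces exp(interval coefficient)
    eff = out["effects"]
    iv = eff[eff["covariate"] == "Timeinterval"]
    for name in ("MORNING", "MIDDAY", "EVENING", "NIGHT"):
        expect = np.exp(coef.loc[f"Timeinterval[{name}]", "estimate"])
        got = iv["predicted_mean"].iloc[
            ["MORNING", "MIDDAY", "EVENING", "NIGHT"].index(name)]
        assert got == pytest.approx(expect)


# --------------------------------------------------- direct count simulation


def test_simulated_zero_fraction_matches_closed_form():
    spec = ModelSpec(terms=("Temperature", "Timeinterval"))
    true = ZinbParams(beta=np.array([0.0, 0.3, 0.3, 0.3, 0.3]), gamma=-0.08,
                      phi=2.0, sigma_colony=1e-8, sigma_season=0.0)
    rows, truth = simulate_glmm_counts(spec, true, n_colonies=2, n_seasons=1,
                                       n_days_per_season=300, seed=21)
    design = truth["design"]
    mu = np.exp(design.X @ true.beta)  # u ~ 0
    p = 1.0 / (1.0 + np.exp(-true.gamma * design.hour))
    p0 = np.exp(zinb1_logpmf(np.zeros_like(mu), mu, true.phi, p))
    for h in (0, 6, 12, 18, 23):
        m = design.hour == h
        emp = (design.y[m] == 0).mean()
        expect = p0[m].mean()
        mc = 3 * np.sqrt(expect * (1 - expect) / m.sum())
        assert abs(emp - expect) < mc + 1e-12


def test_poisson_limit_dispersion_near_one():
    spec = ModelSpec(terms=("Timeinterval",))
    true = ZinbParams(beta=np.array([1.0, 1.0, 1.0, 1.0]), gamma=-50.0,
                      phi=1.0, sigma_colony=1e-9, sigma_season=0.0)
    rows, truth = simulate_glmm_counts(spec, true, n_colonies=2, n_seasons=1,
                                       n_days_per_season=200, seed=22)
    y = truth["design"].y
    assert y.var() / y.mean() == pytest.approx(1.0, abs=0.08)


def test_total_zero_inflation_gives_all_zeros():
    spec = ModelSpec(terms=("Timeinterval",))
    true = ZinbParams(beta=np.ones(4), gamma=50.0, phi=2.0,
                      sigma_colony=0.1, sigma_season=0.0)
    rows, truth = simulate_glmm_counts(spec, true, n_colonies=2, n_seasons=1,
                                       n_days_per_season=5, seed=23)
    y = truth["design"].y
    assert (y[truth["design"].hour > 0] == 0).all()
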