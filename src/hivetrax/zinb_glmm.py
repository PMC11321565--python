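"""Zero-inflated negative-binomial (NB1) mixed model for hourly entrance counts.

Model
-----
The response is the hourly registration count per hive.  Conditional on
random intercepts ``u`` the count is zero-inflated NB1:

* structural-zero probability  ``logit p_i = gamma * hour_i``  (numeric hour
  0-23, no intercept) — reader saturation makes whole hours drop out more
  often when traffic is high, and traffic tracks the diurnal clock;
* count part  ``log mu_i = x_i' beta + u_colony(i) + u_season(i)`` with the
  NB1 parameterisation ``Var(y|u) = phi * mu`` (``phi >= 1``), i.e. a
  negative binomial with size ``r = mu/(phi-1)`` and success probability
  ``1/phi``;
* independent normal random intercepts for colony and season (crossed).

The marginal likelihood integrates the random intercepts out with a joint
Laplace approximation at the mode of the penalised log-likelihood; the mode
is found by damped Newton steps on the (small) random-effect vector.
Fixed effects, the zero-inflation slope, ``log(phi-1)`` and the log standard
deviations are then maximised by L-BFGS-B.

Fixed-effect vocabulary: Age, Temperature, Light, Wind, Rain, Timeinterval
(four cell means, no global intercept), Subspecies (single contrast,
Buck = 0), the Subspecies:covariate interactions and Temperature:Light.
Environmental covariates are centred at their analysis-set means; Age and
Hour are left on their natural scales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, psi

from .events_io import INTERVALS

__all__ = [
    "ModelSpec",
    "ZinbDesign",
    "ZinbParams",
    "GlmmFit",
    "DRONE_MAXIMAL",
    "DRONE_FINAL",
    "WORKER_FINAL",
    "default_candidates",
    "build_design",
    "negloglik",
    "fit",
    "vif",
    "select_model",
    "infer",
    "effect_grid",
]

_CONTINUOUS = ("Age", "Temperature", "Light", "Wind", "Rain")
_ENVIRONMENTAL = ("Temperature", "Light", "Wind", "Rain")
_COLUMN_OF = {
    "Age": "age",
    "Temperature": "temperature",
    "Light": "light",
    "Wind": "wind",
    "Rain": "rain_sum",
}

_MAXIMAL_TERMS = (
    "Age", "Temperature", "Light", "Wind", "Rain", "Timeinterval", "Subspecies",
    "Subspecies:Age", "Subspecies:Temperature", "Subspecies:Light",
    "Subspecies:Wind", "Subspecies:Rain", "Temperature:Light",
)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate fixed-effect structure.

    All candidates share the zero-inflation term (numeric hour, no
    intercept) and the crossed colony/season random intercepts; only the
    fixed terms vary during model selection.
    """

    terms: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.terms) - set(_MAXIMAL_TERMS)
        if bad:
            raise ValueError(f"unknown model terms: {sorted(bad)}")


DRONE_MAXIMAL = ModelSpec(terms=_MAXIMAL_TERMS, name="drone-maximal")
#: The selected drone model: no rain main effect or subspecies:rain
#: interaction, but with the temperature x light interaction.
DRONE_FINAL = ModelSpec(
    terms=(
        "Age", "Temperature", "Light", "Wind", "Timeinterval", "Subspecies",
        "Subspecies:Age", "Subspecies:Temperature", "Subspecies:Light",
        "Subspecies:Wind", "Temperature:Light",
    ),
    name="drone-final",
)
#: Worker model variant: keeps rain and its subspecies interaction.
WORKER_FINAL = ModelSpec(terms=_MAXIMAL_TERMS, name="worker-final")


def default_candidates(worker: bool = False) -> list[ModelSpec]:
    """Backward-selection candidate set: the maximal model, the rain-family
    drop, the temperature:light drop, and both drops combined."""
    drop_rain = tuple(t for t in _MAXIMAL_TERMS if t not in ("Rain", "Subspecies:Rain"))
    drop_tl = tuple(t for t in _MAXIMAL_TERMS if t != "Temperature:Light")
    drop_both = tuple(t for t in drop_rain if t != "Temperature:Light")
    cands = [
        DRONE_MAXIMAL,
        ModelSpec(terms=drop_rain, name="drop-rain"),
        ModelSpec(terms=drop_tl, name="drop-temp-light"),
        ModelSpec(terms=drop_both, name="drop-both"),
    ]
    if worker:
        cands[0] = replace(cands[0], name="worker-maximal")
    return cands


@dataclass
class ZinbDesign:
    """Numeric design for one analysis set (NA rows removed listwise)."""

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    hour: np.ndarray
    colony_idx: np.ndarray
    season_idx: np.ndarray
    n_colony: int
    n_season: int
    colony_levels: list[str]
    season_levels: list[str]
    centring: dict[str, float]
    n_dropped: int = 0
    spec: ModelSpec | None = None

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_params(self) -> int:
        # beta, gamma, log(phi-1), log sigma_colony [, log sigma_season]
        return self.n_fixed + 3 + (1 if self.n_season > 0 else 0)


@dataclass
class ZinbParams:
    beta: np.ndarray
    gamma: float
    phi: float
    sigma_colony: float
    sigma_season: float = 0.0

    def pack(self, design: ZinbDesign) -> np.ndarray:
        out = [np.asarray(self.beta, dtype=float), [self.gamma],
               [np.log(max(self.phi - 1.0, 1e-12))],
               [np.log(max(self.sigma_colony, 1e-12))]]
        if design.n_season > 0:
            out.append([np.log(max(self.sigma_season, 1e-12))])
        return np.concatenate(out)


def _unpack(theta: np.ndarray, design: ZinbDesign) -> ZinbParams:
    p = design.n_fixed
    gamma = float(theta[p])
    phi = 1.0 + float(np.exp(np.clip(theta[p + 1], -700, 50)))
    s_c = float(np.exp(np.clip(theta[p + 2], -700, 50)))
    s_s = float(np.exp(np.clip(theta[p + 3], -700, 50))) if design.n_season > 0 else 0.0
    return ZinbParams(beta=np.asarray(theta[:p], dtype=float), gamma=gamma, phi=phi,
                      sigma_colony=s_c, sigma_season=s_s)


def build_design(
    rows: pd.DataFrame,
    spec: ModelSpec,
) -> ZinbDesign:
    """Design matrices for the hourly count table.

    Rows with NA count or NA covariates are excluded listwise (their number
    is recorded on the result).  Environmental covariates are centred at
    their analysis-set means; the stored centring constants allow
    predictions on the original scales.  ``Timeinterval`` expands to four
    indicator columns (cell means, no global intercept) and ``Subspecies``
    to a single Mel-vs-Buck contrast column.
    """
    needed = sorted({_COLUMN_OF[t] for t in _CONTINUOUS})
    df = rows.dropna(subset=["count", *needed]).reset_index(drop=True)
    n_dropped = len(rows) - len(df)
    if len(df) == 0:
        raise ValueError("no complete rows")

    centring: dict[str, float] = {}
    values: dict[str, np.ndarray] = {}
    for term in _CONTINUOUS:
        col = df[_COLUMN_OF[term]].to_numpy(dtype=float)
        if term in _ENVIRONMENTAL:
            centring[term] = float(col.mean())
            col = col - centring[term]
        values[term] = col
    subspecies = (df["subspecies"].to_numpy() == "Mel").astype(float)
    if "Subspecies" in spec.terms and len(np.unique(subspecies)) < 2:
        raise ValueError("term Subspecies has no variation in the analysis set")

    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in spec.terms:
        if term == "Timeinterval":
            for iv in INTERVALS:
                cols.append((df["interval"].to_numpy() == iv).astype(float))
                names.append(f"Timeinterval[{iv}]")
        elif term == "Subspecies":
            cols.append(subspecies)
            names.append("Subspecies[Mel]")
        elif ":" in term:
            a, b = term.split(":")
            va = subspecies if a == "Subspecies" else values[a]
            vb = subspecies if b == "Subspecies" else values[b]
            cols.append(va * vb)
            names.append(term)
        else:
            cols.append(values[term])
            names.append(term)
        if np.ptp(cols[-1]) == 0:
            raise ValueError(f"term {term!r} has no variation in the analysis set")
    X = np.column_stack(cols)

    colony_levels = sorted(df["hive_id"].astype(str).unique())
    season_levels = sorted(df["season"].astype(str).unique())
    colony_idx = df["hive_id"].astype(str).map({c: i for i, c in enumerate(colony_levels)})
    season_idx = df["season"].astype(str).map({s: i for i, s in enumerate(season_levels)})
    return ZinbDesign(
        y=df["count"].to_numpy(dtype=float),
        X=X,
        colnames=names,
        hour=df["hour"].to_numpy(dtype=float),
        colony_idx=colony_idx.to_numpy(dtype=np.int64),
        season_idx=season_idx.to_numpy(dtype=np.int64),
        n_colony=len(colony_levels),
        # a single-season table has no identifiable season intercept
        n_season=len(season_levels) if len(season_levels) > 1 else 0,
        colony_levels=colony_levels,
        season_levels=season_levels,
        centring=centring,
        n_dropped=n_dropped,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# conditional likelihood


def zinb1_logpmf(y: np.ndarray, mu: np.ndarray, phi: float, p_zero: np.ndarray) -> np.ndarray:
    """Log pmf of the zero-inflated NB1 mixture (elementwise).

    ``P(0) = p + (1-p) NB(0 | mu, phi)`` and ``P(k>0) = (1-p) NB(k)`` with
    ``Var = phi * mu``.  The ``phi -> 1`` limit is the zero-inflated
    Poisson, taken exactly when ``phi - 1 < 1e-10``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    p_zero = np.broadcast_to(np.asarray(p_zero, dtype=float), y.shape)
    with np.errstate(divide="ignore"):
        logp = np.log(p_zero)
        log1m = np.log1p(-p_zero)
    out = np.empty_like(y)
    iz = y == 0
    if phi - 1.0 < 1e-10:
        lz = -mu
        lp = y * np.log(mu) - mu - gammaln(y + 1.0)
    else:
        c = np.log(phi) / (phi - 1.0)
        r = mu / (phi - 1.0)
        lz = -c * mu
        lp = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
              - r * np.log(phi) + y * (np.log(phi - 1.0) - np.log(phi)))
    out[iz] = np.logaddexp(logp[iz], log1m[iz] + lz[iz])
    out[~iz] = log1m[~iz] + lp[~iz]
    return out


def _trigamma(x: np.ndarray) -> np.ndarray:
    """Vectorised trigamma via upward recurrence + asymptotic series.

    Accurate to ~1e-12 for x > 0; considerably faster than the generic
    polygamma route, which matters inside the inner Newton loop.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    xs = x.copy()
    for _ in range(8):
        m = xs < 8.0
        if not m.any():
            break
        out[m] += 1.0 / (xs[m] * xs[m])
        xs[m] += 1.0
    inv = 1.0 / xs
    inv2 = inv * inv
    out += inv * (1.0 + 0.5 * inv + inv2 * (1.0 / 6.0 - inv2 * (
        1.0 / 30.0 - inv2 * (1.0 / 42.0 - inv2 / 30.0))))
    return out


def _tetragamma(x: np.ndarray) -> np.ndarray:
    """Vectorised psi''(x) via upward recurrence + asymptotic series."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    xs = x.copy()
    for _ in range(8):
        m = xs < 8.0
        if not m.any():
            break
        out[m] -= 2.0 / xs[m] ** 3
        xs[m] += 1.0
    inv = 1.0 / xs
    inv2 = inv * inv
    out -= inv2 * (1.0 + inv * (1.0 + inv * (0.5 + inv2 * (
        -1.0 / 6.0 + inv2 * (1.0 / 6.0 - 0.3 * inv2)))))
    return out


def _cond_terms(
    y: np.ndarray,
    eta: np.ndarray,
    logp: np.ndarray,
    log1m: np.ndarray,
    phi: float,
    iz: np.ndarray,
    lgam_y1: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Conditional log-likelihood and its first/second derivatives in eta."""
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    n = len(y)
    ll = np.empty(n)
    w1 = np.empty(n)
    w2 = np.empty(n)
    ip = ~iz
    poisson = phi - 1.0 < 1e-10
    c = 1.0 if poisson else np.log(phi) / (phi - 1.0)

    mu_z = mu[iz]
    ll0 = np.logaddexp(logp[iz], log1m[iz] - c * mu_z)
    BA = np.exp(log1m[iz] - c * mu_z - ll0)  # (1-p)NB0 / mixture
    pA = np.exp(logp[iz] - ll0)
    cmu = c * mu_z
    ll[iz] = ll0
    w1[iz] = -cmu * BA
    w2[iz] = -cmu * BA + cmu * cmu * pA * BA

    mu_p = mu[ip]
    y_p = y[ip]
    if poisson:
        ll[ip] = log1m[ip] + y_p * np.log(mu_p) - mu_p - lgam_y1[ip]
        w1[ip] = y_p - mu_p
        w2[ip] = -mu_p
    else:
        r = mu_p / (phi - 1.0)
        ll[ip] = (log1m[ip] + gammaln(y_p + r) - gammaln(r) - lgam_y1[ip]
                  - r * np.log(phi) + y_p * (np.log(phi - 1.0) - np.log(phi)))
        d1 = (psi(y_p + r) - psi(r)) / (phi - 1.0) - c
        d2 = (_trigamma(y_p + r) - _trigamma(r)) / (phi - 1.0) ** 2
        w1[ip] = mu_p * d1
        w2[ip] = mu_p * d1 + mu_p * mu_p * d2
    return float(ll.sum()), w1, w2


def _cond_extras(
    y: np.ndarray,
    eta: np.ndarray,
    hour: np.ndarray,
    logp: np.ndarray,
    log1m: np.ndarray,
    phi: float,
    iz: np.ndarray,
) -> tuple[np.ndarray, ...]:
    """Third eta-derivative and the explicit gamma/rho partials of the
    conditional log-likelihood and of its first two eta-derivatives.

    These feed the analytic gradient of the Laplace objective (the
    log-determinant correction needs d^3 ll / d eta^3 and the dependence of
    the curvature weights on the zero-inflation slope and ``log(phi-1)``).
    """
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    n = len(y)
    w3 = np.empty(n)
    v1 = np.zeros(n)
    dw1dg = np.zeros(n)
    dw2dg = np.zeros(n)
    r1 = np.zeros(n)
    dw1dr = np.zeros(n)
    dw2dr = np.zeros(n)
    ip = ~iz
    poisson = phi - 1.0 < 1e-10
    c = 1.0 if poisson else np.log(phi) / (phi - 1.0)
    p_all = np.exp(logp)

    # zero rows: ll = log(p + (1-p) e^{-t}) with t = c*mu
    mu_z = mu[iz]
    t = c * mu_z
    ll0 = np.logaddexp(logp[iz], log1m[iz] - t)
    b = np.exp(log1m[iz] - t - ll0)  # (1-p)e^{-t} / mixture
    bb = b * np.exp(logp[iz] - ll0)  # b(1-b); 1-b = p/A
    w3[iz] = -bb * (1.0 - 2.0 * b) * t**3 + 3.0 * bb * t**2 - b * t
    pz = p_all[iz]
    h_z = hour[iz]
    E = np.exp(-t)
    A = np.exp(ll0)
    dpdg = h_z * pz * (1.0 - pz)
    v1[iz] = (1.0 - E) / A * dpdg
    dbdg = -E / (A * A) * dpdg
    dw1dg[iz] = -t * dbdg
    dw2dg[iz] = ((1.0 - 2.0 * b) * t * t - t) * dbdg
    if not poisson:
        pm1 = phi - 1.0
        dcdphi = (pm1 / phi - np.log(phi)) / pm1**2
        dtdr = mu_z * dcdphi * pm1
        r1[iz] = -b * dtdr
        dw1dr[iz] = (bb * t - b) * dtdr
        dw2dr[iz] = (-(1.0 - 2.0 * b) * bb * t * t + 3.0 * bb * t - b) * dtdr

    # positive rows
    mu_p = mu[ip]
    y_p = y[ip]
    if poisson:
        w3[ip] = -mu_p
        v1[ip] = -hour[ip] * p_all[ip]
    else:
        pm1 = phi - 1.0
        r = mu_p / pm1
        A1 = psi(y_p + r) - psi(r)
        A2 = _trigamma(y_p + r) - _trigamma(r)
        A3 = _tetragamma(y_p + r) - _tetragamma(r)
        lp1 = A1 / pm1 - c
        lp2 = A2 / pm1**2
        lp3 = A3 / pm1**3
        w3[ip] = mu_p * lp1 + 3.0 * mu_p**2 * lp2 + mu_p**3 * lp3
        v1[ip] = -hour[ip] * p_all[ip]
        dcdphi = (pm1 / phi - np.log(phi)) / pm1**2
        dlldphi = -r / pm1 * (A1 - np.log(phi)) - r / phi + y_p / pm1 - y_p / phi
        r1[ip] = dlldphi * pm1
        dw1dr[ip] = mu_p * pm1 * (-(A2 * r + A1) / pm1**2 - dcdphi)
        dw2dr[ip] = dw1dr[ip] - mu_p**2 * (A3 * r + 2.0 * A2) / pm1**2
    return w3, v1, dw1dg, dw2dg, r1, dw1dr, dw2dr


# ---------------------------------------------------------------------------
# Laplace approximation


def _laplace(
    theta: np.ndarray,
    design: ZinbDesign,
    u0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_newton: int = 60,
    want_grad: bool = False,
) -> tuple[float, np.ndarray] | tuple[float, np.ndarray, np.ndarray]:
    """Laplace-approximate marginal log-likelihood and the random-effect mode.

    With ``want_grad`` the exact gradient of the Laplace objective with
    respect to the packed parameter vector is returned as well (envelope
    term for the penalised log-likelihood plus implicit differentiation of
    the log-determinant correction through the mode).
    """
    par = _unpack(theta, design)
    nc, ns = design.n_colony, design.n_season
    q = nc + ns
    u = np.zeros(q) if u0 is None else u0.copy()
    y, X, hour = design.y, design.X, design.hour
    c_idx, s_idx = design.colony_idx, design.season_idx
    iz = y == 0
    lgam_y1 = gammaln(y + 1.0)
    gh = par.gamma * hour
    logp = -np.logaddexp(0.0, -gh)
    log1m = -np.logaddexp(0.0, gh)
    Xb = X @ par.beta
    var_c = par.sigma_colony**2
    var_s = par.sigma_season**2 if ns > 0 else 1.0
    inv_c = 1.0 / max(var_c, 1e-300)
    inv_s = 1.0 / max(var_s, 1e-300)

    def eta_of(u: np.ndarray) -> np.ndarray:
        e = Xb + u[c_idx]
        if ns > 0:
            e = e + u[nc + s_idx]
        return e

    def penalty(u: np.ndarray) -> float:
        pen = 0.5 * inv_c * float(u[:nc] @ u[:nc]) \
            + 0.5 * nc * np.log(2 * np.pi * var_c)
        if ns > 0:
            pen += 0.5 * inv_s * float(u[nc:] @ u[nc:]) \
                + 0.5 * ns * np.log(2 * np.pi * var_s)
        return pen

    ll, w1, w2 = _cond_terms(y, eta_of(u), logp, log1m, par.phi, iz, lgam_y1)
    J = ll - penalty(u)
    lam = 0.0
    for _ in range(max_newton):
        g = np.empty(q)
        g[:nc] = np.bincount(c_idx, weights=w1, minlength=nc) - inv_c * u[:nc]
        if ns > 0:
            g[nc:] = np.bincount(s_idx, weights=w1, minlength=ns) - inv_s * u[nc:]
        if np.max(np.abs(g)) < tol:
            break
        H = np.zeros((q, q))
        dc = np.bincount(c_idx, weights=w2, minlength=nc)
        H[:nc, :nc] = np.diag(dc - inv_c)
        if ns > 0:
            dsn = np.bincount(s_idx, weights=w2, minlength=ns)
            H[nc:, nc:] = np.diag(dsn - inv_s)
            cross = np.bincount(c_idx * ns + s_idx, weights=w2,
                                minlength=nc * ns).reshape(nc, ns)
            H[:nc, nc:] = cross
            H[nc:, :nc] = cross.T
        # damped Newton: maximize J, -H should be positive definite
        improved = False
        for _trial in range(25):
            try:
                step = np.linalg.solve(-H + lam * np.eye(q), g)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-6)
                continue
            u_new = u + step
            ll_new, w1_new, w2_new = _cond_terms(
                y, eta_of(u_new), logp, log1m, par.phi, iz, lgam_y1
            )
            J_new = ll_new - penalty(u_new)
            if np.isfinite(J_new) and J_new >= J - 1e-12:
                u, J, w1, w2 = u_new, J_new, w1_new, w2_new
                lam = lam / 10.0 if lam > 1e-12 else 0.0
                improved = True
                break
            lam = max(lam * 10.0, 1e-6)
        if not improved:
            break

    # curvature at the mode for the Laplace correction
    H = np.zeros((q, q))
    dc = np.bincount(c_idx, weights=w2, minlength=nc)
    H[:nc, :nc] = np.diag(dc - inv_c)
    if ns > 0:
        dsn = np.bincount(s_idx, weights=w2, minlength=ns)
        H[nc:, nc:] = np.diag(dsn - inv_s)
        cross = np.bincount(c_idx * ns + s_idx, weights=w2,
                            minlength=nc * ns).reshape(nc, ns)
        H[:nc, nc:] = cross
        H[nc:, :nc] = cross.T
    sign, logdet = np.linalg.slogdet(-H)
    if sign <= 0:
        sign, logdet = np.linalg.slogdet(-H + 1e-8 * np.eye(q))
        if sign <= 0:
            if want_grad:
                return -np.inf, np.zeros(len(theta)), u
            return -np.inf, u
    marg = J + 0.5 * q * np.log(2 * np.pi) - 0.5 * logdet
    if not want_grad:
        return float(marg), u

    G = -H
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.inv(G + 1e-8 * np.eye(q))
    w3, v1, dw1dg, dw2dg, r1, dw1dr, dw2dr = _cond_extras(
        y, eta_of(u), hour, logp, log1m, par.phi, iz
    )
    if ns > 0:
        s_row = Ginv[c_idx, c_idx] + Ginv[nc + s_idx, nc + s_idx] \
            + 2.0 * Ginv[c_idx, nc + s_idx]
    else:
        s_row = Ginv[c_idx, c_idx]
    sw3 = s_row * w3
    a = np.empty(q)
    a[:nc] = np.bincount(c_idx, weights=sw3, minlength=nc)
    if ns > 0:
        a[nc:] = np.bincount(s_idx, weights=sw3, minlength=ns)
    m = Ginv @ a
    Zm = m[c_idx] + (m[nc + s_idx] if ns > 0 else 0.0)

    X = design.X
    g_beta = X.T @ w1 + 0.5 * (X.T @ sw3 + X.T @ (w2 * Zm))
    g_gamma = float(v1.sum() + 0.5 * (s_row @ dw2dg + dw1dg @ Zm))
    g_rho = float(r1.sum() + 0.5 * (s_row @ dw2dr + dw1dr @ Zm))
    g_lsc = float((u[:nc] @ u[:nc]) * inv_c - nc
                  + inv_c * np.trace(Ginv[:nc, :nc])
                  + inv_c * (u[:nc] @ m[:nc]))
    grad = [g_beta, [g_gamma], [g_rho], [g_lsc]]
    if ns > 0:
        g_lss = float((u[nc:] @ u[nc:]) * inv_s - ns
                      + inv_s * np.trace(Ginv[nc:, nc:])
                      + inv_s * (u[nc:] @ m[nc:]))
        grad.append([g_lss])
    return float(marg), np.concatenate(grad), u


def negloglik(
    params: ZinbParams | np.ndarray,
    design: ZinbDesign,
    u0: np.ndarray | None = None,
) -> float:
    """Negative Laplace-approximate marginal log-likelihood.

    Non-finite evaluations return a large finite penalty so optimisers can
    recover.
    """
    theta = params.pack(design) if isinstance(params, ZinbParams) else np.asarray(params, float)
    try:
        marg, _ = _laplace(theta, design, u0=u0)
    except (FloatingPointError, np.linalg.LinAlgError):
        return 1e12
    if not np.isfinite(marg):
        return 1e12
    return -marg


@dataclass
class GlmmFit:
    """Fitted zero-inflated NB1 mixed model."""

    params: ZinbParams
    beta: pd.Series
    gamma: float
    phi: float
    sigma2_colony: float
    sigma2_season: float
    loglik: float
    aic: float
    cov: np.ndarray  # covariance of the packed parameter vector
    df: np.ndarray | None  # Satterthwaite effective df per packed parameter
    param_names: list[str]
    design: ZinbDesign
    u_hat: np.ndarray
    converged: bool
    boundary: dict[str, bool]
    message: str = ""
    n_free: int = 0

    def se(self) -> np.ndarray:
        d = np.diag(self.cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)


def _start_values(design: ZinbDesign) -> np.ndarray:
    y = design.y
    # crude fixed-effect start: least squares on log(y + 0.5)
    target = np.log(y + 0.5)
    beta, *_ = np.linalg.lstsq(design.X, target, rcond=None)
    ratio = y.var() / max(y.mean(), 1e-8)
    phi0 = float(np.clip(ratio, 1.2, 50.0))
    theta = [beta, [-0.02], [np.log(phi0 - 1.0)], [np.log(0.3)]]
    if design.n_season > 0:
        theta.append([np.log(0.3)])
    return np.concatenate(theta)


def fit(
    design: ZinbDesign,
    start: np.ndarray | None = None,
    seed: int = 0,
    maxiter: int = 400,
    n_restarts: int = 2,
    compute_cov: bool = True,
) -> GlmmFit:
    """Maximise the Laplace marginal likelihood by quasi-Newton (L-BFGS-B).

    The inner random-effect mode is warm-started across objective
    evaluations.  If the optimiser fails, up to ``n_restarts`` perturbed
    restarts are attempted; a non-convergent result is returned with
    ``converged=False``, never silently.
    """
    rank = np.linalg.matrix_rank(design.X)
    if rank < design.n_fixed:
        raise ValueError("fixed-effect design is rank deficient")
    theta0 = _start_values(design) if start is None else np.asarray(start, dtype=float)
    p = design.n_fixed
    cache = {"u": np.zeros(design.n_colony + design.n_season)}

    # Whiten the fixed-effect block (QR of the design) and rescale the
    # zero-inflation slope: the raw covariates live on wildly different
    # scales (days, W/m^2, km/h, hours) and are correlated, which stalls the
    # quasi-Newton line search in the natural parameterisation.
    k = len(theta0)
    n = design.n_obs
    R = np.linalg.qr(design.X / np.sqrt(n), mode="r")
    hour_scale = float(design.hour.std()) or 1.0
    M = np.zeros((k, k))  # theta_natural = M @ theta_whitened
    M[:p, :p] = np.linalg.inv(R)
    M[p, p] = 1.0 / hour_scale
    for j in range(p + 1, k):
        M[j, j] = 1.0

    def value_and_grad(theta_nat: np.ndarray) -> tuple[float, np.ndarray]:
        marg, grad, u = _laplace(theta_nat, design, u0=cache["u"], want_grad=True)
        if not np.isfinite(marg):
            return 1e12, np.zeros_like(theta_nat)
        cache["u"] = u
        return -marg, -grad

    def objective_white(theta_w: np.ndarray) -> tuple[float, np.ndarray]:
        f, g = value_and_grad(M @ theta_w)
        return f, M.T @ g

    bounds = [(None, None)] * p + [(-10.0 * hour_scale, 10.0 * hour_scale),
                                   (-20.0, 10.0), (-10.0, 5.0)]
    if design.n_season > 0:
        bounds.append((-10.0, 5.0))

    rng = np.random.default_rng(seed)
    theta0_w = np.linalg.solve(M, theta0)
    best = None
    message = ""
    for attempt in range(1 + n_restarts):
        t0 = theta0_w if attempt == 0 else theta0_w + rng.normal(0, 0.2, size=k)
        res = optimize.minimize(
            objective_white, t0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
            message = str(res.message)
        if res.success:
            break
    assert best is not None
    theta = M @ np.asarray(best.x, dtype=float)
    par = _unpack(theta, design)
    marg, u_hat = _laplace(theta, design)
    k = design.n_params
    names = [*design.colnames, "zi_hour", "log(phi-1)", "log_sd_colony"]
    if design.n_season > 0:
        names.append("log_sd_season")

    cov = np.full((len(theta), len(theta)), np.nan)
    df = None
    if compute_cov:
        grad_w = lambda t: objective_white(t)[1]  # noqa: E731
        theta_w = np.linalg.solve(M, theta)
        cov_w = _fd_covariance_from_grad(grad_w, theta_w)
        cov = M @ cov_w @ M.T
        df = _satterthwaite_df(grad_w, theta_w, cov_w, M, design)
    boundary = {
        "sigma_colony": theta[p + 2] <= -10.0 + 1e-6,
        "sigma_season": design.n_season > 0 and theta[p + 3] <= -10.0 + 1e-6,
    }
    return GlmmFit(
        params=par,
        beta=pd.Series(par.beta, index=design.colnames),
        gamma=par.gamma,
        phi=par.phi,
        sigma2_colony=par.sigma_colony**2,
        sigma2_season=par.sigma_season**2,
        loglik=float(marg),
        aic=float(-2.0 * marg + 2.0 * k),
        cov=cov,
        df=df,
        param_names=names,
        design=design,
        u_hat=u_hat,
        converged=bool(best.success),
        boundary=boundary,
        message=message,
        n_free=k,
    )


def _satterthwaite_df(grad_w, theta_w: np.ndarray, cov_w: np.ndarray,
                      M: np.ndarray, design: ZinbDesign,
                      rel_step: float = 0.05) -> np.ndarray:
    """Satterthwaite-type effective degrees of freedom per packed parameter.

    With only a handful of colony and season levels, the sampling
    uncertainty of the variance components inflates the tails of the Wald
    ratios for cluster-confounded fixed effects (the interval cell means and
    the subspecies contrast).  Following the usual Satterthwaite recipe,
    ``df_j = 2 V_jj^2 / Var(V_jj)`` where ``Var(V_jj)`` is obtained by the
    delta method: the gradient of ``V_jj`` with respect to the log standard
    deviations (finite differences of the observed information) combined
    with their estimated covariance.  Coefficients whose variance does not
    depend on the variance components get a large df (the Wald ratio is
    effectively normal).
    """
    k = len(theta_w)
    p = design.n_fixed
    var_idx = [p + 2] + ([p + 3] if design.n_season > 0 else [])
    cov_nat = M @ cov_w @ M.T
    grads = []  # dV/dlambda for each variance parameter, natural scale
    for i in var_idx:
        h = rel_step * max(1.0, abs(theta_w[i]))
        e = np.zeros(k)
        e[i] = h
        cov_plus = M @ _fd_covariance_from_grad(grad_w, theta_w + e) @ M.T
        grads.append((np.diag(cov_plus) - np.diag(cov_nat)) / h)
    G = np.array(grads)  # (n_var, k)
    C_lam = cov_nat[np.ix_(var_idx, var_idx)]
    V = np.diag(cov_nat)
    var_of_v = np.einsum("ij,ik,kj->j", G, C_lam, G)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * V**2 / var_of_v
    big = design.n_obs - design.n_params
    df = np.where(~np.isfinite(df) | (df > big), big, df)
    return np.maximum(df, 1.0)


def _fd_covariance_from_grad(grad_fn, theta: np.ndarray,
                             rel_step: float = 1e-5) -> np.ndarray:
    """Inverse observed information: central differences of an analytic gradient."""
    n = len(theta)
    H = np.empty((n, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(theta[i]))
        e = np.zeros(n)
        e[i] = h
        H[:, i] = (grad_fn(theta + e) - grad_fn(theta - e)) / (2.0 * h)
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# collinearity, selection, inference


def vif(rows: pd.DataFrame, covariates: Sequence[str] = ("age", "temperature", "light",
                                                          "wind", "rain_sum")) -> pd.Series:
    """Variance inflation factors from the non-interaction design.

    Each covariate is regressed (with intercept) on the remaining ones;
    ``VIF = 1/(1-R^2)``, infinite for perfectly collinear columns.
    """
    df = rows.dropna(subset=list(covariates))
    if len(covariates) < 2:
        raise ValueError("need at least two covariates")
    M = df[list(covariates)].to_numpy(dtype=float)
    n = len(M)
    out = {}
    for j, name in enumerate(covariates):
        yj = M[:, j]
        Xj = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def select_model(
    rows: pd.DataFrame,
    candidates: Sequence[ModelSpec],
    seed: int = 0,
    **fit_kw,
) -> tuple[pd.DataFrame, ModelSpec, dict[str, GlmmFit]]:
    """Fit every candidate on the identical analysis set and rank by AIC.

    Ties (AIC within 1e-6) are broken toward fewer parameters; candidates
    that fail to converge are excluded from the ranking with a warning
    column, never ranked.
    """
    if not candidates:
        raise ValueError("no candidates")
    fits: dict[str, GlmmFit] = {}
    rows_aic = []
    for i, spec in enumerate(candidates):
        name = spec.name or f"candidate{i}"
        design = build_design(rows, spec)
        f = fit(design, seed=seed, compute_cov=False, **fit_kw)
        fits[name] = f
        rows_aic.append(
            {"model": name, "n_terms": len(spec.terms), "k": f.n_free,
             "loglik": f.loglik, "aic": f.aic, "converged": f.converged}
        )
    tab = pd.DataFrame(rows_aic)
    ok = tab[tab["converged"]]
    if ok.empty:
        raise RuntimeError("no candidate converged")
    ok = ok.sort_values(["aic", "k"], kind="stable")
    tol = 1e-6
    best_aic = float(ok["aic"].iloc[0])
    tied = ok[ok["aic"] <= best_aic + tol].sort_values("k", kind="stable")
    best_name = str(tied["model"].iloc[0])
    chosen = next(s for i, s in enumerate(candidates)
                  if (s.name or f"candidate{i}") == best_name)
    tab = tab.sort_values(["aic"], kind="stable").reset_index(drop=True)
    return tab, chosen, fits


def infer(glmm_fit: GlmmFit, level: float = 0.95) -> dict[str, pd.DataFrame]:
    """Wald inference tables for a converged fit.

    Returns ``coefficients`` (estimate, SE, CI, z, p for every packed
    parameter), ``deviance`` (per-term Wald chi-square, grouping the four
    interval cell means into one term) and ``effects`` (predicted mean
    counts over each covariate by subspecies, other covariates at their
    reference/centring values).
    """
    f = glmm_fit
    se = f.se()
    theta = f.params.pack(f.design)
    if f.df is not None:
        q = stats.t.ppf(0.5 + level / 2.0, f.df)
        df_col = f.df
    else:
        q = stats.norm.ppf(0.5 + level / 2.0)
        df_col = np.inf
    coef = pd.DataFrame(
        {
            "term": f.param_names,
            "estimate": theta,
            "se": se,
            "df": df_col,
            "ci_low": theta - q * se,
            "ci_high": theta + q * se,
        }
    )
    coef["z"] = coef["estimate"] / coef["se"]
    if f.df is not None:
        coef["p"] = 2.0 * stats.t.sf(np.abs(coef["z"]), f.df)
    else:
        coef["p"] = 2.0 * stats.norm.sf(np.abs(coef["z"]))
    coef["significant"] = (coef["ci_low"] > 0) | (coef["ci_high"] < 0)

    # per-term Wald chi-square on the fixed effects
    groups: dict[str, list[int]] = {}
    for i, name in enumerate(f.design.colnames):
        term = "Timeinterval" if name.startswith("Timeinterval[") else name.replace("[Mel]", "")
        groups.setdefault(term, []).append(i)
    groups["zi_hour"] = [len(f.design.colnames)]
    dev_rows = []
    singular = False
    for term, idx in groups.items():
        b = theta[idx]
        V = f.cov[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            chi2, singular = np.nan, True
        dev_rows.append(
            {"term": term, "chisq": chi2, "df": len(idx),
             "p": float(stats.chi2.sf(chi2, len(idx))) if np.isfinite(chi2) else np.nan}
        )
    deviance = pd.DataFrame(dev_rows)
    if singular:
        deviance.attrs["unreliable"] = True
    effects = effect_grid(f)
    return {"coefficients": coef, "deviance": deviance, "effects": effects}


def effect_grid(glmm_fit: GlmmFit, n_points: int = 25) -> pd.DataFrame:
    """Predicted mean counts along each continuous covariate by subspecies.

    All other covariates sit at their reference values (centring point for
    the environmental variables, age 0, MIDDAY interval, random effects 0);
    at the reference point itself the prediction for each interval equals
    ``exp`` of that interval's cell mean, by construction.
    """
    f = glmm_fit
    design = f.design
    spec = design.spec
    assert spec is not None
    names = design.colnames
    beta = f.params.beta

    def predict(row_vals: Mapping[str, float]) -> float:
        x = np.zeros(len(names))
        for i, nm in enumerate(names):
            x[i] = row_vals.get(nm, 0.0)
        return float(np.exp(x @ beta))

    rows = []
    present = [t for t in _CONTINUOUS if t in spec.terms]
    ref_interval = "MIDDAY" if "Timeinterval" in spec.terms else None
    for term in present:
        col = _COLUMN_OF[term]
        # grid over the observed (original-scale) range
        centre = design.centring.get(term, 0.0)
        obs = design.X[:, names.index(term)] + centre
        grid = np.linspace(float(obs.min()), float(obs.max()), n_points)
        for ss, ss_val in (("Buck", 0.0), ("Mel", 1.0)):
            for v in grid:
                vals: dict[str, float] = {term: v - centre, "Subspecies[Mel]": ss_val}
                inter = f"Subspecies:{term}"
                if inter in names:
                    vals[inter] = ss_val * (v - centre)
                if ref_interval is not None:
                    vals[f"Timeinterval[{ref_interval}]"] = 1.0
                rows.append(
                    {"covariate": term, "value": float(v), "subspecies": ss,
                     "predicted_mean": predict(vals)}
                )
    # interval-wise predictions at the reference point
    if "Timeinterval" in (spec.terms if spec else ()):
        for iv in INTERVALS:
            rows.append(
                {"covariate": "Timeinterval", "value": float(INTERVALS.index(iv)),
                 "subspecies": "Buck",
                 "predicted_mean": float(np.exp(beta[names.index(f"Timeinterval[{iv}]")]))}
            )
    return pd.DataFrame(rows)
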