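"""Count GLMMs with crossed night/transect random intercepts.

Observation model (log link): y_i | u, v ~ F(mu_i) with
eta_i = x_i' beta + u_{night(i)} + v_{transect(i)},
u_j ~ N(0, sigma_night^2), v_k ~ N(0, sigma_transect^2) (crossed), and F
either Poisson or the type-1 negative binomial (NB1): mean mu, variance
phi * mu with dispersion phi >= 1.  NB1 is realized as a gamma-mixed
Poisson with shape mu/(phi - 1) and scale (phi - 1); phi -> 1 recovers
Poisson.

Estimation is maximum likelihood with a Laplace approximation over the
stacked random effects: the inner mode is found by damped Newton iterations
on the penalized log-likelihood, and the outer optimization runs quasi-Newton
on (beta, log sigma_night, log sigma_transect, log(phi - 1)).  A product
Gauss-Hermite quadrature evaluator (exact up to quadrature order, feasible
for a handful of random-effect levels) is provided as an independent check
of the Laplace approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .design import DESIGN_COLUMNS, Design, ModelSpec, build_design

__all__ = [
    "GlmmFit",
    "LrtResult",
    "TERM_DROPS",
    "fit_all_models",
    "fit_glmm",
    "fit_nb1_glmm",
    "fit_poisson_glmm",
    "lrt",
    "lrt_term",
    "marginal_loglik_quadrature",
    "nb1_logpmf",
    "overdispersion_ratio",
    "predict_activity",
    "rnb1",
]

_ETA_CLIP = 30.0
_SIGMA_FLOOR = np.exp(-6.0)        # effective zero for a random-effect SD


# ---------------------------------------------------------------------------
# observation families


def nb1_logpmf(y, mu, phi):
    """Log pmf of the NB1 distribution (mean mu, variance phi * mu)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if phi < 1:
        raise ValueError("phi must be >= 1")
    if phi == 1.0:
        return stats.poisson.logpmf(y, mu)
    a = phi - 1.0
    r = mu / a
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + y * np.log(a / phi)
        - r * np.log(phi)
    )


def rnb1(mu, phi, rng, size=None):
    """Draw NB1 counts via the gamma-Poisson mixture (phi = 1 -> Poisson)."""
    rng = np.random.default_rng(rng)
    mu = np.asarray(mu, dtype=float)
    if size is None:
        size = mu.shape if mu.shape else None
    if phi < 1:
        raise ValueError("phi must be >= 1")
    if phi == 1.0:
        return rng.poisson(mu, size=size)
    lam = rng.gamma(shape=mu / (phi - 1.0), scale=phi - 1.0, size=size)
    return rng.poisson(lam)


def _family_loglik(y, eta, family, phi):
    """Per-observation log-likelihood only (no derivatives)."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    if family == "poisson" or phi <= 1.0:
        return y * eta - mu - special.gammaln(y + 1)
    a = phi - 1.0
    r = mu / a
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + y * np.log(a / phi)
        - r * np.log(phi)
    )


def _family_terms(y, eta, family, phi):
    """Per-observation loglik and its first/second derivatives wrt eta."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    if family == "poisson":
        ll = y * eta - mu - special.gammaln(y + 1)
        return ll, y - mu, -mu
    a = phi - 1.0
    if a <= 0:
        ll = y * eta - mu - special.gammaln(y + 1)
        return ll, y - mu, -mu
    r = mu / a
    g = special.digamma(y + r) - special.digamma(r) - np.log(phi)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + y * np.log(a / phi)
        - r * np.log(phi)
    )
    d1 = r * g
    d2 = r * g + r * r * (special.polygamma(1, y + r) - special.polygamma(1, r))
    return ll, d1, d2


def _family_terms_ext(y, eta, family, phi):
    """Loglik with derivatives up to third order in eta, plus phi
    derivatives of the loglik and its first two eta-derivatives (NB1)."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    zeros = np.zeros_like(mu)
    if family == "poisson" or phi <= 1.0:
        ll = y * eta - mu - special.gammaln(y + 1)
        return {
            "ll": ll, "d1": y - mu, "d2": -mu, "d3": -mu,
            "dll_dphi": zeros, "dd1_dphi": zeros, "dd2_dphi": zeros,
        }
    a = phi - 1.0
    r = mu / a
    psi0 = special.digamma(y + r) - special.digamma(r)
    g = psi0 - np.log(phi)
    delta1 = special.polygamma(1, y + r) - special.polygamma(1, r)
    delta2 = special.polygamma(2, y + r) - special.polygamma(2, r)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + y * np.log(a / phi)
        - r * np.log(phi)
    )
    d1 = r * g
    d2 = r * g + r * r * delta1
    d3 = r * g + 3 * r * r * delta1 + r**3 * delta2
    # phi-derivatives (dr/dphi = -r/a)
    dll_dphi = -(r / a) * g + y * (1.0 / a - 1.0 / phi) - r / phi
    dd1_dphi = -(r / a) * g - (r * r / a) * delta1 - r / phi
    dd2_dphi = dd1_dphi - (2 * r * r * delta1 + r**3 * delta2) / a
    return {
        "ll": ll, "d1": d1, "d2": d2, "d3": d3,
        "dll_dphi": dll_dphi, "dd1_dphi": dd1_dphi, "dd2_dphi": dd2_dphi,
    }


# ---------------------------------------------------------------------------
# Laplace machinery


def _laplace_loglik(
    beta, sigma_n, sigma_t, phi, design: Design, y, family, u0=None,
    return_mode=False,
):
    """Laplace-approximate marginal log-likelihood.

    Random-effect blocks with SD below the floor are treated as absent.
    """
    X = design.X
    eta_fixed = X @ beta
    use_n = sigma_n is not None and sigma_n > _SIGMA_FLOOR / 2
    use_t = sigma_t is not None and sigma_t > _SIGMA_FLOOR / 2
    ni, ti = design.night_index, design.transect_index
    qn = design.n_nights if use_n else 0
    qt = design.n_transects if use_t else 0
    q = qn + qt

    if q == 0:
        ll, _, _ = _family_terms(y, eta_fixed, family, phi)
        total = float(np.sum(ll))
        if return_mode:
            return total, np.zeros(0), None
        return total

    prec = np.concatenate(
        [
            np.full(qn, 1.0 / sigma_n**2) if use_n else np.zeros(0),
            np.full(qt, 1.0 / sigma_t**2) if use_t else np.zeros(0),
        ]
    )
    u = np.zeros(q) if u0 is None or u0.shape != (q,) else u0.copy()

    def eta_of(u):
        eta = eta_fixed.copy()
        if use_n:
            eta += u[:qn][ni]
        if use_t:
            eta += u[qn:][ti]
        return eta

    def penalized(u):
        ll, d1, d2 = _family_terms(y, eta_of(u), family, phi)
        pen = float(np.sum(ll)) - 0.5 * float(np.dot(prec * u, u))
        return pen, d1, d2

    def grad_of(u, d1):
        g = np.zeros(q)
        if use_n:
            g[:qn] = np.bincount(ni, weights=d1, minlength=qn)
        if use_t:
            g[qn:] = np.bincount(ti, weights=d1, minlength=qt)
        return g - prec * u

    def hess_of(c):
        # H = Z' diag(c) Z + diag(prec), assembled densely (q is small)
        H = np.zeros((q, q))
        if use_n:
            H[:qn, :qn][np.diag_indices(qn)] = np.bincount(
                ni, weights=c, minlength=qn
            )
        if use_t:
            H[qn:, qn:][np.diag_indices(qt)] = np.bincount(
                ti, weights=c, minlength=qt
            )
        if use_n and use_t:
            cross = np.zeros((qn, qt))
            np.add.at(cross, (ni, ti), c)
            H[:qn, qn:] = cross
            H[qn:, :qn] = cross.T
        H[np.diag_indices(q)] += prec
        return H

    pen, d1, d2 = penalized(u)
    for _ in range(100):
        g = grad_of(u, d1)
        if np.max(np.abs(g)) < 1e-9 * (1.0 + abs(pen)):
            break
        c = np.clip(-d2, 1e-12, None)
        H = hess_of(c)
        try:
            cf = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            H[np.diag_indices(q)] += 1e-6 + np.abs(H).max() * 1e-10
            cf = np.linalg.cholesky(H)
        step = np.linalg.solve(cf.T, np.linalg.solve(cf, g))
        s = 1.0
        for _ in range(40):
            u_new = u + s * step
            pen_new, d1_new, d2_new = penalized(u_new)
            if pen_new >= pen - 1e-13:
                break
            s *= 0.5
        else:
            break  # no ascent direction found; accept current mode
        improved = pen_new - pen
        u, pen, d1, d2 = u_new, pen_new, d1_new, d2_new
        if improved < 1e-13 and s < 1.0:
            break

    c = np.clip(-d2, 1e-12, None)
    H = hess_of(c)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        H[np.diag_indices(q)] += 1e-8
        sign, logdet = np.linalg.slogdet(H)
    log_prior_norm = 0.0
    if use_n:
        log_prior_norm += qn * np.log(2 * np.pi * sigma_n**2)
    if use_t:
        log_prior_norm += qt * np.log(2 * np.pi * sigma_t**2)
    ll_marg = (
        pen - 0.5 * log_prior_norm + 0.5 * q * np.log(2 * np.pi) - 0.5 * logdet
    )
    if return_mode:
        return float(ll_marg), u, H
    return float(ll_marg)


def _laplace_loglik_grad(
    beta, sigma_n, sigma_t, phi, design: Design, y, family,
    want_sn, want_st, want_phi,
):
    """Laplace marginal loglik and its analytic gradient.

    Differentiates the approximation exactly, including the dependence of
    the log-determinant on the mode (implicit-function theorem; third
    eta-derivatives of the observation loglik enter here).  Gradient is
    with respect to (beta, log sigma_night, log sigma_transect,
    log(phi - 1)), including only the requested blocks.
    """
    X = design.X
    n, p = X.shape
    ll0, u_hat, _ = _laplace_loglik(
        beta, sigma_n, sigma_t, phi, design, y, family, return_mode=True
    )
    use_n = sigma_n is not None and sigma_n > _SIGMA_FLOOR / 2
    use_t = sigma_t is not None and sigma_t > _SIGMA_FLOOR / 2
    ni, ti = design.night_index, design.transect_index
    qn = design.n_nights if use_n else 0
    qt = design.n_transects if use_t else 0
    q = qn + qt

    eta = X @ beta
    if use_n:
        eta = eta + u_hat[:qn][ni]
    if use_t:
        eta = eta + u_hat[qn:][ti]
    ext = _family_terms_ext(y, eta, family, phi)
    d1, d2, d3 = ext["d1"], ext["d2"], ext["d3"]

    if q == 0:
        grads = [X.T @ d1]
        if want_sn:
            grads.append(np.zeros(1))
        if want_st:
            grads.append(np.zeros(1))
        if want_phi:
            grads.append(np.array([np.sum(ext["dll_dphi"]) * (phi - 1.0)]))
        return float(np.sum(ext["ll"])), np.concatenate(grads)

    prec = np.concatenate(
        [
            np.full(qn, 1.0 / sigma_n**2) if use_n else np.zeros(0),
            np.full(qt, 1.0 / sigma_t**2) if use_t else np.zeros(0),
        ]
    )
    c = np.clip(-d2, 1e-12, None)
    H = np.zeros((q, q))
    if use_n:
        H[:qn, :qn][np.diag_indices(qn)] = np.bincount(
            ni, weights=c, minlength=qn
        )
    if use_t:
        H[qn:, qn:][np.diag_indices(qt)] = np.bincount(
            ti, weights=c, minlength=qt
        )
    if use_n and use_t:
        cross = np.zeros((qn, qt))
        np.add.at(cross, (ni, ti), c)
        H[:qn, qn:] = cross
        H[qn:, :qn] = cross.T
    H[np.diag_indices(q)] += prec
    Hinv = np.linalg.inv(H)

    def zrows(M):
        """(Z M)_i for a (q, k) matrix: sum the night and transect rows."""
        out = np.zeros((n,) + M.shape[1:])
        if use_n:
            out += M[:qn][ni]
        if use_t:
            out += M[qn:][ti]
        return out

    # S_i = (Z Hinv Z')_ii
    S = np.zeros(n)
    if use_n:
        S += Hinv[np.ix_(range(qn), range(qn))][ni, ni]
    if use_t:
        S += np.diag(Hinv)[qn:][ti]
    if use_n and use_t:
        S += 2.0 * Hinv[:qn, qn:][ni, ti]

    def zt(v):
        """Z' v: aggregate an n-vector over night and transect levels."""
        parts = []
        if use_n:
            parts.append(np.bincount(ni, weights=v, minlength=qn))
        if use_t:
            parts.append(np.bincount(ti, weights=v, minlength=qt))
        return np.concatenate(parts)

    # columns of B = d(grad_u)/d(theta); M = Hinv @ B; deta = direct + Z M
    cols = []
    direct_eta = []         # d eta_i / d theta_j at fixed u
    direct_grad = []        # d g / d theta_j at fixed u (and fixed eta)
    extra_tr = []           # -(1/2) tr(Hinv dP/dtheta) and phi diag terms

    for j in range(p):
        cols.append(zt(d2 * X[:, j]))
        direct_eta.append(X[:, j])
        direct_grad.append(float(X[:, j] @ d1))
        extra_tr.append(0.0)
    if want_sn and use_n:
        b = np.zeros(q)
        b[:qn] = 2.0 * prec[:qn] * u_hat[:qn]
        cols.append(b)
        direct_eta.append(np.zeros(n))
        direct_grad.append(
            float(np.sum(prec[:qn] * u_hat[:qn] ** 2)) - qn
        )
        extra_tr.append(float(np.sum(np.diag(Hinv)[:qn] * prec[:qn])))
    elif want_sn:
        cols.append(np.zeros(q))
        direct_eta.append(np.zeros(n))
        direct_grad.append(0.0)
        extra_tr.append(0.0)
    if want_st and use_t:
        b = np.zeros(q)
        b[qn:] = 2.0 * prec[qn:] * u_hat[qn:]
        cols.append(b)
        direct_eta.append(np.zeros(n))
        direct_grad.append(
            float(np.sum(prec[qn:] * u_hat[qn:] ** 2)) - qt
        )
        extra_tr.append(float(np.sum(np.diag(Hinv)[qn:] * prec[qn:])))
    elif want_st:
        cols.append(np.zeros(q))
        direct_eta.append(np.zeros(n))
        direct_grad.append(0.0)
        extra_tr.append(0.0)
    if want_phi:
        cols.append(zt(ext["dd1_dphi"]))
        direct_eta.append(np.zeros(n))
        direct_grad.append(float(np.sum(ext["dll_dphi"])))
        extra_tr.append(0.5 * float(np.sum(ext["dd2_dphi"] * S)))

    B = np.column_stack(cols)
    M = Hinv @ B
    deta = np.column_stack(direct_eta) + zrows(M)
    chain = 0.5 * (d3 * S) @ deta
    grad = np.array(direct_grad) + chain + np.array(extra_tr)
    if want_phi:
        grad[-1] *= phi - 1.0      # chain rule to log(phi - 1)
    return float(ll0), grad


def marginal_loglik_quadrature(
    beta, sigma_n, sigma_t, phi, design: Design, y, family="nb1", order=15,
    chunk=200_000,
):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    The random-effect integral is evaluated on a product Gauss-Hermite grid
    centered at the joint posterior mode and scaled by the Cholesky factor
    of the inverse curvature (adaptive GH), which keeps the nodes inside
    the integrand's peak regardless of how concentrated the posterior is.
    The integrand itself is evaluated exactly, so this is an independent
    oracle for the Laplace approximation.  Cost grows as
    ``order ** (n_nights + n_transects)``: toy designs only.
    """
    X = design.X
    eta_fixed = X @ beta
    ni, ti = design.night_index, design.transect_index
    use_n = sigma_n is not None and sigma_n > 0
    use_t = sigma_t is not None and sigma_t > 0
    qn = design.n_nights if use_n else 0
    qt = design.n_transects if use_t else 0
    q = qn + qt
    if q == 0:
        return float(np.sum(_family_loglik(y, eta_fixed, family, phi)))
    if order**q > 5e7:
        raise ValueError("quadrature grid too large; reduce the toy design")

    # mode and curvature from the Laplace machinery (integration variables
    # only; the integrand below is evaluated exactly)
    _, u_hat, H = _laplace_loglik(
        beta, sigma_n if use_n else None, sigma_t if use_t else None,
        phi, design, y, family, return_mode=True,
    )
    L = np.linalg.cholesky(np.linalg.inv(H))

    prec = np.concatenate(
        [
            np.full(qn, 1.0 / sigma_n**2) if use_n else np.zeros(0),
            np.full(qt, 1.0 / sigma_t**2) if use_t else np.zeros(0),
        ]
    )
    log_prior_norm = -0.5 * float(np.sum(np.log(2 * np.pi / prec)))

    def log_integrand(U):
        """h(u) = sum_i log f(y_i | u) + log prior(u), for rows of U."""
        eta = np.tile(eta_fixed, (U.shape[0], 1))
        if use_n:
            eta += U[:, :qn][:, ni]
        if use_t:
            eta += U[:, qn:][:, ti]
        ll = _family_loglik(y[None, :], eta, family, phi)
        pen = -0.5 * np.sum(prec * U * U, axis=1)
        return ll.sum(axis=1) + pen + log_prior_norm

    x_gh, w_gh = np.polynomial.hermite.hermgauss(order)
    log_w1 = np.log(w_gh) + x_gh**2
    sign, logdet_cov_half = np.linalg.slogdet(L)
    assert sign > 0
    log_const = 0.5 * q * np.log(2.0) + logdet_cov_half

    # iterate the product grid in chunks
    total_terms = []
    n_nodes = order**q
    idx = np.arange(n_nodes)
    for lo in range(0, n_nodes, chunk):
        sel = idx[lo: lo + chunk]
        digits = np.empty((sel.size, q), dtype=int)
        rem = sel.copy()
        for d in range(q - 1, -1, -1):
            digits[:, d] = rem % order
            rem //= order
        Z = x_gh[digits]                       # (m, q)
        U = u_hat[None, :] + np.sqrt(2.0) * Z @ L.T
        logw = log_w1[digits].sum(axis=1)
        total_terms.append(logw + log_integrand(U))
    return float(special.logsumexp(np.concatenate(total_terms)) + log_const)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GlmmFit:
    """A fitted count GLMM."""

    beta: np.ndarray
    columns: tuple[str, ...]
    sigma_night: float
    sigma_transect: float
    phi: float | None
    loglik: float
    converged: bool
    family: str
    design: Design
    u_night: np.ndarray
    v_transect: np.ndarray
    vcov: np.ndarray | None = None
    phi_at_boundary: bool = False
    n_obs: int = 0
    message: str = ""

    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=list(self.columns))

    def fitted_eta(self, conditional: bool = True) -> np.ndarray:
        eta = self.design.X @ self.beta
        if conditional:
            if self.u_night.size:
                eta = eta + self.u_night[self.design.night_index]
            if self.v_transect.size:
                eta = eta + self.v_transect[self.design.transect_index]
        return eta

    def fitted_mu(self, conditional: bool = True) -> np.ndarray:
        return np.exp(np.clip(self.fitted_eta(conditional), -_ETA_CLIP, _ETA_CLIP))


def _init_beta_phi(y, X):
    """Starting values from a fixed-effects-only Poisson GLM."""
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        beta0 = np.asarray(res.params, dtype=float)
        mu = np.clip(np.asarray(res.fittedvalues), 1e-8, None)
    except Exception:
        beta0 = np.zeros(X.shape[1])
        beta0[0] = np.log(np.mean(y) + 0.5)
        mu = np.full_like(y, np.exp(beta0[0]), dtype=float)
    dof = max(len(y) - X.shape[1], 1)
    pearson = float(np.sum((y - mu) ** 2 / mu) / dof)
    phi0 = float(np.clip(pearson, 1.05, 100.0))
    beta0 = np.clip(beta0, -20, 20)
    return beta0, phi0


def fit_glmm(
    records,
    spec: ModelSpec | None = None,
    *,
    family: str | None = None,
    drop_columns: tuple[str, ...] = (),
    include_night: bool = True,
    include_transect: bool = True,
    phi_fixed: float | None = None,
    compute_vcov: bool = False,
    maxiter: int = 400,
    start: dict | None = None,
) -> GlmmFit:
    """Fit a Poisson or NB1 GLMM with crossed night/transect intercepts.

    ``records`` may be NightRecords, a records DataFrame, or a prebuilt
    :class:`~batpass.design.Design` carrying counts.  ``drop_columns``
    removes fixed-effect columns (nested reduced models for LRTs);
    ``include_night``/``include_transect`` disable a variance component
    (sigma fixed at zero, giving a plain regression when both are off).
    """
    if isinstance(records, Design):
        design = records
        if drop_columns:
            design = design.subset(
                tuple(c for c in design.columns if c not in drop_columns)
            )
        spec = design.spec
    else:
        spec = spec or ModelSpec()
        if drop_columns:
            cols = tuple(c for c in spec.columns if c not in drop_columns)
            spec = ModelSpec(
                response=spec.response,
                temp_center_c=spec.temp_center_c,
                family=spec.family,
                columns=cols,
            )
        design = build_design(records, spec)
    family = family or spec.family
    if family not in ("poisson", "nb1"):
        raise ValueError("family must be 'poisson' or 'nb1'")
    y = design.y
    if y is None:
        raise ValueError("records carry no counts to fit")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    X = design.X
    nbeta = X.shape[1]

    beta0, phi0 = _init_beta_phi(y, X)
    estimate_phi = family == "nb1" and phi_fixed is None
    start = start or {}
    if "beta" in start:
        given = start["beta"]
        beta0 = np.array(
            [given.get(c, 0.0) for c in design.columns]
            if isinstance(given, dict)
            else given,
            dtype=float,
        )
    sn0 = float(start.get("sigma_night", 0.1))
    st0 = float(start.get("sigma_transect", 0.1))
    if "phi" in start:
        phi0 = float(start["phi"])

    p0 = list(beta0)
    bounds: list[tuple[float, float]] = [(-30.0, 30.0)] * nbeta
    slot_sn = slot_st = slot_phi = None
    if include_night:
        slot_sn = len(p0)
        p0.append(np.log(np.clip(sn0, 5e-3, 15.0)))
        bounds.append((-6.0, 3.0))
    if include_transect:
        slot_st = len(p0)
        p0.append(np.log(np.clip(st0, 5e-3, 15.0)))
        bounds.append((-6.0, 3.0))
    if estimate_phi:
        slot_phi = len(p0)
        p0.append(np.log(np.clip(phi0 - 1.0, 1e-3, 400.0)))
        bounds.append((-8.0, 6.0))
    p0 = np.array(p0)

    def unpack(p):
        beta = p[:nbeta]
        sn = float(np.exp(p[slot_sn])) if slot_sn is not None else None
        st = float(np.exp(p[slot_st])) if slot_st is not None else None
        if family == "poisson":
            phi = 1.0
        elif estimate_phi:
            phi = 1.0 + float(np.exp(p[slot_phi]))
        else:
            phi = float(phi_fixed)
        return beta, sn, st, phi

    # NOTE: the inner mode search always cold-starts so that the objective
    # is a deterministic function of p; the gradient is the exact analytic
    # derivative of the Laplace approximation.
    def nll(p):
        beta, sn, st, phi = unpack(p)
        ll, grad = _laplace_loglik_grad(
            beta, sn, st, phi, design, y, family,
            include_night, include_transect, estimate_phi,
        )
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(p)
        return -ll, -grad

    res = optimize.minimize(
        nll,
        p0,
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 20000, "ftol": 1e-12,
                 "gtol": 1e-7},
    )
    p_hat = res.x
    beta, sn, st, phi = unpack(p_hat)
    ll, u_mode, _ = _laplace_loglik(
        beta, sn, st, phi, design, y, family, return_mode=True
    )

    use_n = include_night and sn is not None and sn > _SIGMA_FLOOR / 2
    use_t = include_transect and st is not None and st > _SIGMA_FLOOR / 2
    qn = design.n_nights if use_n else 0
    u_night = u_mode[:qn] if use_n else np.zeros(0)
    v_transect = u_mode[qn:] if use_t else np.zeros(0)

    sn_out = sn if include_night else 0.0
    st_out = st if include_transect else 0.0
    # SDs optimized to the floor are reported as zero
    if include_night and sn is not None and sn <= _SIGMA_FLOOR * 1.01:
        sn_out = 0.0
    if include_transect and st is not None and st <= _SIGMA_FLOOR * 1.01:
        st_out = 0.0
    phi_boundary = bool(
        estimate_phi and p_hat[slot_phi] <= bounds[slot_phi][0] + 1e-6
    )

    vcov = None
    if compute_vcov:
        vcov = _beta_vcov(lambda p: nll(p)[0], p_hat, nbeta)

    return GlmmFit(
        beta=np.asarray(beta, dtype=float),
        columns=design.columns,
        sigma_night=float(sn_out),
        sigma_transect=float(st_out),
        phi=float(phi) if family == "nb1" else None,
        loglik=float(ll),
        converged=bool(res.success),
        family=family,
        design=design,
        u_night=u_night,
        v_transect=v_transect,
        vcov=vcov,
        phi_at_boundary=phi_boundary,
        n_obs=len(y),
        message=str(res.message),
    )


def _beta_vcov(nll, p_hat, nbeta):
    """Fixed-effect covariance from the numerical Hessian of the joint nll."""
    npar = len(p_hat)
    steps = 1e-4 * (1.0 + np.abs(p_hat))
    H = np.zeros((npar, npar))
    f0 = nll(p_hat)
    fp = np.empty(npar)
    fm = np.empty(npar)
    for i in range(npar):
        e = np.zeros(npar)
        e[i] = steps[i]
        fp[i] = nll(p_hat + e)
        fm[i] = nll(p_hat - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(npar):
        for j in range(i + 1, npar):
            ei = np.zeros(npar)
            ej = np.zeros(npar)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = nll(p_hat + ei + ej)
            fmm = nll(p_hat - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * steps[i] * steps[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov[:nbeta, :nbeta]


def fit_poisson_glmm(records, spec: ModelSpec | None = None, **kw) -> GlmmFit:
    """Poisson GLMM (exploratory model; see :func:`overdispersion_ratio`)."""
    return fit_glmm(records, spec, family="poisson", **kw)


def fit_nb1_glmm(records, spec: ModelSpec | None = None, **kw) -> GlmmFit:
    """NB1 GLMM: the primary activity model."""
    return fit_glmm(records, spec, family="nb1", **kw)


# ---------------------------------------------------------------------------
# diagnostics, tests, predictions


def overdispersion_ratio(fit: GlmmFit, conditional: bool = True) -> float:
    """Sum of squared Pearson residuals over residual degrees of freedom.

    Degrees of freedom account for fixed effects only.  With ``conditional``
    (default) the fitted means include the predicted random effects.  For a
    Poisson fit a ratio well above 1 indicates overdispersion.
    """
    y = fit.design.y
    mu = fit.fitted_mu(conditional=conditional)
    var = mu if fit.family == "poisson" else (fit.phi or 1.0) * mu
    dof = len(y) - len(fit.columns)
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    return float(np.sum((y - mu) ** 2 / var) / dof)


@dataclass
class LrtResult:
    """A likelihood-ratio test of nested fits."""

    term: str
    statistic: float
    df: int
    p_value: float

    @property
    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


#: Columns removed from the full model when testing each term.  Direct
#: effects drop their interactions as well; interaction tests retain all
#: direct effects.
TERM_DROPS: dict[str, tuple[str, ...]] = {
    "dist_road": (
        "dist_road_100", "dist_road_0",
        "dist_road_100:temp_max", "dist_road_0:temp_max",
        "dist_road_100:site1", "dist_road_0:site1",
        "dist_road_100:site2", "dist_road_0:site2",
    ),
    "temp_max": ("temp_max", "dist_road_100:temp_max", "dist_road_0:temp_max"),
    "dist_road:temp_max": ("dist_road_100:temp_max", "dist_road_0:temp_max"),
    "site": (
        "site1", "site2",
        "dist_road_100:site1", "dist_road_0:site1",
        "dist_road_100:site2", "dist_road_0:site2",
    ),
    "dist_road:site": (
        "dist_road_100:site1", "dist_road_0:site1",
        "dist_road_100:site2", "dist_road_0:site2",
    ),
    "year": ("year",),
    "light": ("light",),
}


def lrt(full: GlmmFit, reduced: GlmmFit, term: str = "") -> LrtResult:
    """Likelihood-ratio test of a reduced model nested in the full model."""
    if full.family != reduced.family:
        raise ValueError("fits use different families")
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits use different data")
    if not set(reduced.columns) < set(full.columns):
        raise ValueError("reduced model is not nested in the full model")
    df = len(full.columns) - len(reduced.columns)
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6 * (1 + abs(full.loglik)):
        warnings.warn(
            f"negative LRT statistic ({stat:.3g}); convergence is suspect",
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    return LrtResult(
        term=term, statistic=float(stat), df=df,
        p_value=float(stats.chi2.sf(stat, df)),
    )


def _start_from(fit: GlmmFit) -> dict:
    return {
        "beta": dict(zip(fit.columns, fit.beta)),
        "sigma_night": max(fit.sigma_night, 5e-3),
        "sigma_transect": max(fit.sigma_transect, 5e-3),
        "phi": fit.phi if fit.phi is not None else 2.0,
    }


def lrt_term(records, spec: ModelSpec | None = None, term: str = "dist_road",
             full: GlmmFit | None = None, **fit_kw) -> LrtResult:
    """Fit full and reduced models for one term and test it.

    To guard against local optima (notably at variance-component
    boundaries), the reduced model is fit both from the default start and
    warm-started from the full fit, keeping the better likelihood; if the
    reduced model still beats the full model, the full model is refit from
    the reduced solution.
    """
    if term not in TERM_DROPS:
        raise ValueError(f"unknown term {term!r}; one of {sorted(TERM_DROPS)}")
    if full is None:
        full = fit_glmm(records, spec, **fit_kw)
    drops = TERM_DROPS[term]
    reduced = fit_glmm(records, spec, drop_columns=drops, **fit_kw)
    warm = fit_glmm(records, spec, drop_columns=drops,
                    start=_start_from(full), **fit_kw)
    if warm.loglik > reduced.loglik:
        reduced = warm
    if reduced.loglik > full.loglik:
        refit = fit_glmm(records, spec, start=_start_from(reduced), **fit_kw)
        if refit.loglik > full.loglik:
            full = refit
    return lrt(full, reduced, term=term)


def predict_activity(
    fit_or_beta,
    dist_road: int,
    site: str = "average",
    year="average",
    light="average",
    temp_c: float | None = None,
    temp_center_c: float = 24.0,
) -> float:
    """Expected passes per night at a covariate setting, random effects at 0.

    ``"average"`` zeroes the sum-contrast columns (grand mean over levels);
    named levels apply the contrast codes.  ``temp_c=None`` evaluates at the
    centering temperature.
    """
    from .design import SITE_CODES, YEAR_CODES

    if isinstance(fit_or_beta, GlmmFit):
        beta = pd.Series(fit_or_beta.beta, index=list(fit_or_beta.columns))
    else:
        b = np.asarray(fit_or_beta, dtype=float)
        if b.shape != (len(DESIGN_COLUMNS),):
            raise ValueError(f"beta must have {len(DESIGN_COLUMNS)} entries")
        beta = pd.Series(b, index=list(DESIGN_COLUMNS))

    if dist_road not in (0, 100, 300):
        raise ValueError("dist_road must be 0, 100 or 300")
    d100 = 1.0 if dist_road == 100 else 0.0
    d0 = 1.0 if dist_road == 0 else 0.0
    if site == "average":
        s1 = s2 = 0.0
    elif site in SITE_CODES:
        s1, s2 = SITE_CODES[site]
    else:
        raise ValueError(f"unknown site {site!r}")
    if year == "average":
        yr = 0.0
    elif int(year) in YEAR_CODES:
        yr = YEAR_CODES[int(year)]
    else:
        raise ValueError(f"unknown year {year!r}")
    if light == "average":
        lt = 0.0
    elif isinstance(light, (bool, np.bool_)):
        lt = -1.0 if light else 1.0
    else:
        raise ValueError("light must be 'average' or a bool")
    temp = 0.0 if temp_c is None else float(temp_c) - temp_center_c

    x = {
        "intercept": 1.0,
        "dist_road_100": d100,
        "dist_road_0": d0,
        "temp_max": temp,
        "dist_road_100:temp_max": d100 * temp,
        "dist_road_0:temp_max": d0 * temp,
        "site1": s1,
        "site2": s2,
        "dist_road_100:site1": d100 * s1,
        "dist_road_0:site1": d0 * s1,
        "dist_road_100:site2": d100 * s2,
        "dist_road_0:site2": d0 * s2,
        "year": yr,
        "light": lt,
    }
    eta = sum(beta[k] * v for k, v in x.items() if k in beta.index)
    return float(np.exp(eta))


def fit_all_models(
    records_by_response: dict[str, object],
    spec: ModelSpec | None = None,
    *,
    min_passes: int = 500,
    excluded_species: tuple[str, ...] = (),
    terms: tuple[str, ...] = tuple(TERM_DROPS),
    **fit_kw,
):
    """Fit the NB1 GLMM per response and run the per-term LRTs.

    ``records_by_response`` maps a response name ("all" or a species code)
    to its NightRecords/DataFrame.  Species with fewer than ``min_passes``
    identified passes, or on the exclusion list, are skipped with a recorded
    reason.  Returns (fits, coefficient table, LRT table, exclusions).
    """
    fits: dict[str, GlmmFit] = {}
    exclusions: dict[str, str] = {}
    lrt_rows = []
    for name, recs in records_by_response.items():
        from .design import records_frame

        df = records_frame(recs)
        total = int(df["count"].sum())
        if name != "all":
            if name in excluded_species:
                exclusions[name] = "on exclusion list"
                continue
            if total < min_passes:
                exclusions[name] = f"only {total} identified passes (< {min_passes})"
                continue
        fit = fit_nb1_glmm(df, spec, **fit_kw)
        fits[name] = fit
        for term in terms:
            r = lrt_term(df, spec, term=term, full=fit, **fit_kw)
            lrt_rows.append(
                {"response": name, "term": term, "statistic": r.statistic,
                 "df": r.df, "p_value": r.p_value, "stars": r.stars}
            )
    coef = pd.DataFrame({name: fit.coef() for name, fit in fits.items()})
    lrt_table = pd.DataFrame(lrt_rows)
    return fits, coef, lrt_table, exclusions
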