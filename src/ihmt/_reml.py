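"""Restricted maximum likelihood for variance-component models.

Fits models of the form

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, s_k^2 I),  e ~ N(0, s_e^2 I)

by minimising the (optionally penalised) REML criterion over
log-standard-deviation parameters.  An optional gamma prior on each
random-effect standard deviation regularises components away from the
zero boundary.  Satterthwaite-type denominator degrees of freedom are
provided for F-tests of fixed-effect contrasts, following the
eigenvector decomposition used by the standard mixed-model ANOVA
implementations: each one-dimensional component of the contrast gets a
Satterthwaite df from the delta method, and the components are pooled
into a single denominator df.

Problem sizes here are small (N of a few hundred), so V is factored
densely with Cholesky at every objective evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "GammaPrior",
    "RemlFit",
    "reml_fit",
    "satterthwaite_ftest",
    "kr_adjusted_cov",
]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior applied to a random-effect SD."""

    shape: float = 2.0
    rate: float = 0.5

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma prior needs shape > 0 and rate > 0")

    def neg2_log_density(self, sd: float) -> float:
        # constant terms dropped; only the sd-dependent part matters
        return -2.0 * ((self.shape - 1.0) * np.log(sd) - self.rate * sd)


@dataclass
class RemlFit:
    """Result of a (penalised) REML fit."""

    sigmas: np.ndarray        # SDs: one per random component, residual last
    beta: np.ndarray          # GLS fixed-effect estimates
    cov_beta: np.ndarray      # (X' V^-1 X)^-1
    objective: float          # minimised -2 penalised REML log-likelihood
    converged: bool
    n_obs: int
    rank_x: int
    _X: np.ndarray = None     # retained for downstream inference
    _Z: list = None
    _G: list = None
    _y: np.ndarray = None
    _priors: list = None
    _w_cache: np.ndarray = None  # cached Var of the variance estimates

    @property
    def variances(self) -> np.ndarray:
        return self.sigmas**2


def _neg2_reml(
    log_sd: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    G: list[np.ndarray],
    priors: list[GammaPrior | None],
) -> float:
    sd = np.exp(log_sd)
    V = (sd[-1] ** 2) * np.eye(len(y))
    for s, Gk in zip(sd[:-1], G):
        V += (s**2) * Gk
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = linalg.cho_solve((L, True), y)
    Vi_X = linalg.cho_solve((L, True), X)
    A = X.T @ Vi_X
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(A, X.T @ Vi_y)
    ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    out = logdet_v + logdet_a + ypy
    for s, prior in zip(sd[:-1], priors):
        if prior is not None:
            out += prior.neg2_log_density(s)
    return float(out)


def _neg2_reml_valgrad(
    log_sd: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    G: list[np.ndarray],
    priors: list[GammaPrior | None],
) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the penalised -2 REML criterion.

    Uses the standard REML score: d(-2l)/dv_k = tr(P G_k) - y'P G_k P y
    with P the REML projection, chained onto log-SD coordinates.
    """
    sd = np.exp(log_sd)
    n = len(y)
    V = (sd[-1] ** 2) * np.eye(n)
    for s, Gk in zip(sd[:-1], G):
        V += (s**2) * Gk
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return np.inf, np.zeros_like(log_sd)
    Vi = linalg.cho_solve((L, True), np.eye(n))
    Vi_X = Vi @ X
    A = X.T @ Vi_X
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, np.zeros_like(log_sd)
    P = Vi - Vi_X @ np.linalg.solve(A, Vi_X.T)
    Py = P @ y
    value = float(2.0 * np.sum(np.log(np.diag(L))) + logdet_a + y @ Py)

    grad = np.empty(len(sd))
    for k, Gk in enumerate(G):
        grad[k] = np.sum(P * Gk) - float(Py @ Gk @ Py)
    grad[-1] = np.trace(P) - float(Py @ Py)
    grad *= 2.0 * sd**2  # d v / d log sd = 2 v

    for k, prior in enumerate(priors):
        if prior is not None:
            value += float(prior.neg2_log_density(sd[k]))
            grad[k] += -2.0 * (prior.shape - 1.0) + 2.0 * prior.rate * sd[k]
    return value, np.asarray(grad, dtype=float)


def minimize_bounded(fun_valgrad, x0, bounds, args=(), tol: float = 1e-8):
    """Bounded minimisation with a convergence check and fallback.

    L-BFGS-B occasionally reports convergence from the starting point
    with a large gradient (observed with particular bound values); the
    projected gradient is therefore verified and a trust-region solve
    is used as fallback when the first-order condition fails.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    res = optimize.minimize(
        fun_valgrad, x0, args=args, method="L-BFGS-B", jac=True,
        bounds=list(zip(lo, hi)),
        options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
    )

    def proj_grad_norm(x, g):
        pg = g.copy()
        pg[(x <= lo + 1e-12) & (g > 0)] = 0.0
        pg[(x >= hi - 1e-12) & (g < 0)] = 0.0
        return np.max(np.abs(pg))

    val, grad = fun_valgrad(res.x, *args)
    if proj_grad_norm(res.x, grad) <= 1e-4 * max(1.0, abs(val)):
        return res.x, val, True
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="delta_grad == 0.0")
        res2 = optimize.minimize(
            fun_valgrad, res.x if np.isfinite(res.fun) else np.asarray(x0),
            args=args, method="trust-constr", jac=True,
            bounds=optimize.Bounds(lo, hi),
            options={"gtol": 1e-9, "xtol": 1e-12, "maxiter": 1000},
        )
    if res2.fun <= val:
        val2, grad2 = fun_valgrad(res2.x, *args)
        return res2.x, float(res2.fun), proj_grad_norm(res2.x, grad2) <= 1e-3 * max(
            1.0, abs(val2)
        )
    return res.x, val, False


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z: list[np.ndarray],
    priors: list[GammaPrior | None] | None = None,
    start_sd: np.ndarray | None = None,
    tol: float = 1e-8,
) -> RemlFit:
    """Fit the variance-component model by penalised REML.

    Parameters
    ----------
    y, X, Z
        Response, fixed-effect design and list of random-effect
        indicator matrices (one per variance component; the residual is
        implicit).
    priors
        Optional gamma prior per random component (None = unpenalised);
        the residual SD is never penalised.
    start_sd
        Starting SDs (random components + residual).  Defaults to a
        deterministic heuristic from the OLS residual scale.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    rank_x = np.linalg.matrix_rank(X)
    if rank_x < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    if priors is None:
        priors = [None] * len(Z)
    if len(priors) != len(Z):
        raise ValueError("need one prior slot per random component")

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    scale = float(np.std(resid))
    if scale <= 0 or not np.isfinite(scale):
        scale = max(float(np.std(y)), 1e-8)
    if start_sd is None:
        start_sd = np.full(len(Z) + 1, 0.5 * scale)
        start_sd[-1] = scale
    start_sd = np.maximum(np.asarray(start_sd, dtype=float), 1e-8 * scale)

    G = [Zk @ Zk.T for Zk in Z]
    # bounds keep V comfortably invertible; SDs at the lower bound are
    # numerically zero relative to the data scale
    lo, hi = float(np.log(1e-5 * scale)), float(np.log(1e3 * scale))
    x0 = np.clip(np.log(start_sd), lo, hi)
    xhat, fval, ok = minimize_bounded(
        _neg2_reml_valgrad, x0, [(lo, hi)] * len(x0), args=(y, X, G, priors), tol=tol
    )
    if not np.isfinite(fval):
        raise RuntimeError("REML fit failed to converge (non-finite objective)")

    sd = np.exp(xhat)
    V = (sd[-1] ** 2) * np.eye(len(y))
    for s, Gk in zip(sd[:-1], G):
        V += (s**2) * Gk
    L = linalg.cholesky(V, lower=True)
    Vi_X = linalg.cho_solve((L, True), X)
    A = X.T @ Vi_X
    cov_beta = np.linalg.inv(A)
    beta = cov_beta @ (X.T @ linalg.cho_solve((L, True), y))
    return RemlFit(
        sigmas=sd,
        beta=beta,
        cov_beta=cov_beta,
        objective=float(fval),
        converged=bool(ok),
        n_obs=len(y),
        rank_x=rank_x,
        _X=X,
        _Z=Z,
        _G=G,
        _y=y,
        _priors=priors,
    )


def _var_of_variances(fit: RemlFit) -> np.ndarray:
    """Asymptotic covariance of the variance estimates (delta method).

    The Hessian of the -2 penalised REML criterion is taken numerically
    in variance (sigma^2) coordinates; its singular directions (e.g.
    components pinned at the boundary) are handled with a pseudoinverse.
    """
    if fit._w_cache is not None:
        return fit._w_cache
    v_hat = fit.sigmas**2

    def f(v: np.ndarray) -> float:
        return _neg2_reml(0.5 * np.log(np.maximum(v, 1e-300)), fit._y, fit._X,
                          fit._G, fit._priors)

    k = len(v_hat)
    h = np.maximum(1e-4 * v_hat, 1e-12)
    H = np.zeros((k, k))
    f0 = f(v_hat)
    if not np.isfinite(f0):  # degenerate fit (e.g. zero-variance data)
        fit._w_cache = np.zeros((k, k))
        return fit._w_cache
    fp = np.zeros(k)
    fm = np.zeros(k)
    with np.errstate(invalid="ignore", over="ignore"):
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            fp[i] = f(v_hat + e)
            fm[i] = f(np.maximum(v_hat - e, 1e-300))
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = f(v_hat + ei + ej)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + f0
                ) / (h[i] * h[j])
    H[~np.isfinite(H)] = 0.0
    try:
        fit._w_cache = 2.0 * np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        fit._w_cache = np.zeros((k, k))
    return fit._w_cache


def kr_adjusted_cov(fit: RemlFit) -> np.ndarray:
    """Small-sample adjusted covariance of the fixed effects.

    The plug-in GLS covariance (X'V^-1 X)^-1 ignores the uncertainty of
    the estimated variance parameters and is therefore too small in
    finite samples.  This applies the Kenward-Roger inflation
    Phi_A = Phi + 2 Phi Lambda Phi with
    Lambda = sum_ij W_ij (Q_ij - P_i Phi P_j), which is exact to second
    order for covariance structures linear in the variance parameters
    (as here).
    """
    sd = fit.sigmas
    n = fit.n_obs
    V = (sd[-1] ** 2) * np.eye(n)
    for s, Gk in zip(sd[:-1], fit._G):
        V += (s**2) * Gk
    Lc = linalg.cholesky(V, lower=True)
    Vi_X = linalg.cho_solve((Lc, True), fit._X)
    Phi = fit.cov_beta
    W = _var_of_variances(fit)
    Gs = list(fit._G) + [np.eye(n)]
    k = len(Gs)
    T = [Gk @ Vi_X for Gk in Gs]
    U = [linalg.cho_solve((Lc, True), Tk) for Tk in T]
    P = [Vi_X.T @ Tk for Tk in T]
    Lam = np.zeros_like(Phi)
    for i in range(k):
        for j in range(k):
            if W[i, j] == 0:
                continue
            Qij = T[i].T @ U[j]
            Lam += W[i, j] * (Qij - P[i] @ Phi @ P[j])
    return Phi + 2.0 * Phi @ Lam @ Phi


def satterthwaite_ftest(
    fit: RemlFit, L: np.ndarray, cov: np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """F-test of the contrast ``L beta = 0`` with Satterthwaite df.

    ``cov`` optionally replaces the plug-in fixed-effect covariance
    (e.g. the Kenward-Roger adjusted one) in the Wald statistic.
    Returns ``(F, df_num, df_den, p)``.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    C = fit.cov_beta if cov is None else cov
    M = L @ C @ L.T
    Lb = L @ fit.beta
    F = float(Lb @ np.linalg.solve(M, Lb)) / q

    # gradient of each eigen-component's variance wrt the variance params
    var_theta = _var_of_variances(fit)
    d, Q = np.linalg.eigh(M)
    sd = fit.sigmas
    V = (sd[-1] ** 2) * np.eye(fit.n_obs)
    for s, Gk in zip(sd[:-1], fit._G):
        V += (s**2) * Gk
    Lc = linalg.cholesky(V, lower=True)

    nus = []
    for m in range(q):
        if d[m] <= 0:
            continue
        lm = Q[:, m] @ L                      # 1 x p contrast
        h = linalg.cho_solve((Lc, True), fit._X @ (C @ lm))
        grads = np.empty(len(sd))
        for k, Zk in enumerate(fit._Z):
            grads[k] = float(np.sum((Zk.T @ h) ** 2))
        grads[-1] = float(h @ h)
        denom = float(grads @ var_theta @ grads)
        if denom <= 0:
            nus.append(np.inf)
        else:
            nus.append(2.0 * d[m] ** 2 / denom)

    usable = [nu for nu in nus if nu > 2]
    if not usable:
        df_den = float(fit.n_obs - fit.rank_x)
    else:
        E = sum(1.0 if np.isinf(nu) else nu / (nu - 2.0) for nu in usable)
        df_den = 2.0 * E / (E - q) if E > q else float(fit.n_obs - fit.rank_x)
    p = float(stats.f.sf(F, q, df_den))
    return F, float(q), df_den, p
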