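"""Saddlepoint approximation to the likelihood of the observed counts.

With ``x ~ Multinomial(N, pi)`` and ``Y = T X``, the moment generating
function of ``Y`` is ``M_Y(s) = M_X(T's)``, so the cumulant generating
function is ``K_Y(s) = N log( sum_j pi_j exp((T's)_j) )``.  The saddlepoint
density is

``f~(y) = (2 pi)^(-L/2) |K''(s_hat)|^(-1/2) exp{ K(s_hat) - s_hat' y }``

with ``s_hat`` minimizing the convex function ``K(s) - s'y``.  ``pi`` may be
unnormalized over a retained subset of histories: the missing mass then enters
through ``K(0) = N log sum pi < 0``, which is exactly the probability that all
removed categories have zero counts, so forced-zero reduction leaves the
likelihood of the observed data unchanged.

The module also provides the analytic gradient of the log-density with
respect to ``(N, pi)``.  The implicit dependence of ``s_hat`` on the
parameters is handled by the implicit-function theorem, and the log-det term
requires the third cumulant; both reduce to a handful of dense ``L x J``
contractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

LOG_2PI = float(np.log(2.0 * np.pi))


class SaddlepointError(RuntimeError):
    pass


@dataclass
class SaddlepointSolution:
    """Solution of the saddlepoint equation ``K'(s) = y``."""

    s_hat: np.ndarray
    cgf_value: float
    gradient_residual: float
    hessian_logdet: float
    converged: bool
    n_iter: int = 0
    # cached internals reused by the gradient computation
    q: np.ndarray = None
    r: np.ndarray = None
    mu: np.ndarray = None
    hess: np.ndarray = None
    log_s0: float = None


def _cgf_parts(s, N, pi, T_mat):
    """Shared pieces: log S0, softmax weights q, r = exp(u)/S0."""
    u = np.asarray(T_mat.T @ s).ravel()
    with np.errstate(divide="ignore"):
        lw = np.log(pi) + u
    m = lw.max()
    if not np.isfinite(m):
        raise SaddlepointError("all pi entries are zero")
    w = np.exp(lw - m)
    s0 = w.sum()
    log_s0 = m + np.log(s0)
    q = w / s0
    r = np.exp(u - log_s0)
    return log_s0, q, r


def cgf(s, N, pi, T_mat, order: int = 0):
    """``K_Y(s)`` and optionally its gradient and Hessian in ``s``.

    ``order=0`` returns the value, ``order=1`` (value, gradient),
    ``order=2`` (value, gradient, Hessian).  ``pi`` may be unnormalized.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0):
        raise ValueError("pi entries must be nonnegative")
    log_s0, q, _ = _cgf_parts(np.asarray(s, float), N, pi, T_mat)
    value = N * log_s0
    if order == 0:
        return value
    mu = np.asarray(T_mat @ q).ravel()
    grad = N * mu
    if order == 1:
        return value, grad
    Tq = sp.csr_matrix(T_mat).multiply(q[None, :])
    M = np.asarray((Tq @ T_mat.T).todense())
    hess = N * (M - np.outer(mu, mu))
    return value, grad, hess


def _chol_logdet(H, ridge=1e-10):
    """Cholesky factor and log-determinant, with one ridged retry."""
    try:
        c = cho_factor(H, lower=True)
    except np.linalg.LinAlgError:
        c = cho_factor(H + ridge * np.eye(H.shape[0]), lower=True)
    return c, 2.0 * float(np.sum(np.log(np.diag(c[0]))))


def solve_saddlepoint(y, N, pi, T_mat, tol: float = 1e-8,
                      max_iter: int = 100, s0=None,
                      T_dense: np.ndarray = None) -> SaddlepointSolution:
    """Solve ``K'(s) = y`` by damped Newton on the convex ``K(s) - s'y``.

    Starts from ``s = 0`` (or a warm start) and takes trust-region-damped,
    Cholesky-solved Newton steps.  ``tol`` applies to ``||K'(s) - y||_inf``
    relative to the largest observed count (so it is absolute for counts of
    order one).  Non-convergence is flagged, not raised: the caller treats
    such parameter values as (numerically) impossible.  A dense copy of ``T``
    is used for the inner linear algebra whenever it is small enough (BLAS
    beats sparse ops at these sizes).
    """
    y = np.asarray(y, dtype=float)
    tol = tol * max(1.0, float(np.abs(y).max()))
    pi = np.asarray(pi, dtype=float)
    if T_dense is None:
        T_csr = sp.csr_matrix(T_mat)
        if T_csr.shape[0] * T_csr.shape[1] <= 5_000_000:
            T_dense = np.asarray(T_csr.todense())
        op = T_csr if T_dense is None else T_dense
    else:
        op = T_dense
    dense = isinstance(op, np.ndarray)
    L = y.size
    s = np.zeros(L) if s0 is None else np.array(s0, dtype=float)

    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    if not np.any(np.isfinite(logpi)):
        raise SaddlepointError("all pi entries are zero")

    def parts(sv):
        u = op.T @ sv if dense else np.asarray(op.T @ sv).ravel()
        lw = logpi + u
        mx = lw.max()
        w = np.exp(lw - mx)
        ssum = w.sum()
        log_s0 = mx + np.log(ssum)
        q = w / ssum
        return N * log_s0 - sv @ y, log_s0, q, u

    def hessian(q, mu):
        if dense:
            M = (op * q[None, :]) @ op.T
        else:
            M = np.asarray((op.multiply(q[None, :]) @ op.T).todense())
        return N * (M - np.outer(mu, mu))

    f, log_s0, q, u = parts(s)
    resid = np.inf
    H = None
    converged = False
    it = 0
    radius = 1.0  # trust-region radius; adapts to the local nonlinearity
    for it in range(1, max_iter + 1):
        mu = op @ q if dense else np.asarray(op @ q).ravel()
        g = N * mu - y
        resid = float(np.abs(g).max())
        H = hessian(q, mu)
        if resid <= tol:
            converged = True
            break
        try:
            c, _ = _chol_logdet(H)
            newton = -cho_solve(c, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(newton)):
            break
        # trust-region damping: the CGF is extremely non-quadratic far from
        # the optimum and a raw Newton step can overshoot by orders of
        # magnitude; scale to the radius and adapt it by the agreement
        # between actual and model reduction
        accepted = False
        rho = 0.0
        clipped = False
        while radius > 1e-12:
            norm = float(np.linalg.norm(newton))
            clipped = norm > radius
            step = newton * (radius / norm) if clipped else newton
            pred = -(g @ step + 0.5 * step @ (H @ step))
            if pred <= 1e-10 * (abs(f) + 1.0):
                # model reduction below float noise: near convergence the
                # ratio test is meaningless, so take the (tiny) step blindly
                if not clipped and norm < 1e-3:
                    f_new, ls0_new, q_new, u_new = parts(s + step)
                    rho = 1.0
                    accepted = True
                break
            try:
                f_new, ls0_new, q_new, u_new = parts(s + step)
            except (FloatingPointError, SaddlepointError):
                f_new = np.inf
            rho = (f - f_new) / pred if np.isfinite(f_new) else -np.inf
            if rho > 1e-4:
                accepted = True
                break
            radius = min(radius, float(np.linalg.norm(step))) / 4.0
        if not accepted:
            break
        s = s + step
        f, log_s0, q, u = f_new, ls0_new, q_new, u_new
        if rho > 0.75 and clipped:
            radius *= 2.5

    logdet = np.nan
    if converged:
        try:
            _, logdet = _chol_logdet(H)
        except np.linalg.LinAlgError:
            converged = False
    mu = op @ q if dense else np.asarray(op @ q).ravel()
    r = np.exp(u - log_s0)
    return SaddlepointSolution(
        s_hat=s, cgf_value=N * log_s0, gradient_residual=resid,
        hessian_logdet=logdet, converged=converged, n_iter=it,
        q=q, r=r, mu=mu, hess=H, log_s0=log_s0)


def log_saddlepoint_density(y, N, pi, T_mat, sol: SaddlepointSolution = None,
                            **solve_kwargs) -> float:
    """Saddlepoint log-likelihood ``log f~(y; theta)``."""
    y = np.asarray(y, dtype=float)
    if sol is None:
        sol = solve_saddlepoint(y, N, pi, T_mat, **solve_kwargs)
    if not sol.converged:
        raise SaddlepointError("saddlepoint equation did not converge")
    if not np.isfinite(sol.hessian_logdet):
        raise SaddlepointError("CGF Hessian at the saddlepoint is not positive definite")
    L = y.size
    return (-0.5 * L * LOG_2PI - 0.5 * sol.hessian_logdet
            + sol.cgf_value - float(sol.s_hat @ y))


def loglik_gradient_pi_N(y, N, pi, T_mat, sol: SaddlepointSolution,
                         T_dense: np.ndarray = None):
    """Gradient of the saddlepoint log-likelihood w.r.t. ``pi`` and ``N``.

    Uses the converged solution's cached softmax weights.  Returns
    ``(dl_dpi, dl_dN)``.  The saddlepoint's implicit dependence on the
    parameters contributes through ``t_l = tr(G dH/ds_l)`` (third cumulant).
    """
    if not sol.converged:
        raise SaddlepointError("gradient requires a converged saddlepoint solution")
    y = np.asarray(y, dtype=float)
    T_csr = sp.csr_matrix(T_mat)
    Td = np.asarray(T_csr.todense()) if T_dense is None else T_dense
    L = y.size
    q, r, mu, H = sol.q, sol.r, sol.mu, sol.hess

    c, _ = _chol_logdet(H)
    X = cho_solve(c, Td)                      # G T, L x J
    d = np.einsum("lj,lj->j", Td, X)          # d_j = T_j' G T_j
    Gmu = cho_solve(c, mu)
    g1 = Td.T @ Gmu                           # (T' G mu)_j
    tr_gm = float(q @ d)                      # tr(G M)
    muGmu = float(mu @ Gmu)

    t = N * (np.asarray(T_csr @ (q * d)).ravel()
             - tr_gm * mu
             - 2.0 * np.asarray(T_csr @ (q * g1)).ravel()
             + 2.0 * muGmu * mu)
    v = cho_solve(c, t)
    g2 = Td.T @ v
    v_mu = float(v @ mu)

    dl_dpi = N * r * (1.0
                      - 0.5 * (d - tr_gm - 2.0 * g1 + 2.0 * muGmu)
                      + 0.5 * (g2 - v_mu))
    dl_dN = sol.log_s0 - L / (2.0 * N) + 0.5 * v_mu
    return dl_dpi, float(dl_dN)


def penalty(working: np.ndarray, mask: np.ndarray, sigma_p: float = 3.0):
    """Logit-normal penalty ``P = sum logit(theta)^2 / (2 sigma_p^2)``.

    Applies to the probability-type working coordinates (``mask``); acts as
    independent ``N(0, sigma_p^2)`` priors on the logits, keeping estimates
    off the 0/1 boundary (at ``sigma_p = 3``, ~95% prior mass on
    (0.003, 0.997)).  Returns ``(P, dP/dworking)``.
    """
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    working = np.asarray(working, dtype=float)
    wp = np.where(mask, working, 0.0)
    P = float(wp @ wp) / (2.0 * sigma_p ** 2)
    return P, wp / sigma_p ** 2


def aic(loglik: float, n_free_params: int) -> float:
    """Akaike information criterion ``-2 loglik + 2 k``."""
    if not np.isfinite(loglik):
        raise ValueError("loglik must be finite")
    return -2.0 * loglik + 2.0 * n_free_params
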