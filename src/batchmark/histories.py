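"""Latent capture histories and their multinomial cell probabilities.

A latent history ``omega`` is a binary vector of length ``T`` (one bit per
secondary occasion, period-major / occasion-minor).  Histories are indexed
canonically by the integer ``j`` in ``0 .. 2**T - 1`` whose binary expansion,
most-significant bit first, equals ``omega``; this fixed order makes the
columns of the design matrices reproducible.

Cell probabilities follow a POPAN-style entry/survival/capture process:
an individual enters in period ``b`` with probability ``beta_b``, survives
interval ``k -> k+1`` with probability ``phi_k`` (emigration permanent), and
while present is captured on occasion ``(k, t)`` with probability ``p_kt``.
The probability of a history is the sum over all feasible (entry ``b``,
departure ``d``) windows covering its captures:

``pi_omega = sum_{b <= f, d >= l} beta_b * prod_{k=b}^{d} c_k(omega)
  * prod_{k=b}^{d-1} phi_k * (1 - phi_d if d < K)``

with ``c_k`` the within-period Bernoulli product and ``f``/``l`` the first/
last periods with a capture (the all-zero history sums over every ``b <= d``).
"""

from __future__ import annotations

import numpy as np

from .design import StudyDesign
from .parameters import ParameterSet

#: enumerating more than 2**MAX_T histories is refused by default
MAX_T = 24


class DesignTooLargeError(RuntimeError):
    """Raised when a design implies more latent histories than the cap allows."""


def enumerate_histories(design: StudyDesign, max_T: int = MAX_T) -> np.ndarray:
    """All ``2**T`` latent histories as a ``(J, T)`` uint8 bit matrix.

    Row ``j`` is the binary expansion of ``j``, MSB first, so row order is the
    canonical history order.
    """
    T = design.T
    if T > max_T:
        raise DesignTooLargeError(
            f"design has T={T} secondary occasions -> 2**{T} latent histories; "
            f"cap is T <= {max_T}")
    j = np.arange(2 ** T, dtype=np.int64)
    shifts = np.arange(T - 1, -1, -1)
    return ((j[:, None] >> shifts[None, :]) & 1).astype(np.uint8)


def history_index(bits, design: StudyDesign) -> int:
    """Canonical integer index of a history bit vector."""
    bits = np.asarray(bits, dtype=np.int64)
    if bits.size != design.T:
        raise ValueError("history length does not match design")
    return int(bits @ (2 ** np.arange(design.T - 1, -1, -1, dtype=np.int64)))


def first_capture(omega, design: StudyDesign):
    """First-capture ``(period, occasion)`` (1-based) or ``None`` if never caught."""
    bits = np.asarray(omega).ravel()
    if bits.size != design.T:
        raise ValueError("history length does not match design")
    nz = np.flatnonzero(bits)
    if nz.size == 0:
        return None
    pos = int(nz[0])
    for k in range(1, design.K + 1):
        off = design.occasion_offset(k)
        if pos < off + design.Tks[k - 1]:
            return (k, pos - off + 1)
    raise AssertionError("unreachable")


def _period_bounds(design: StudyDesign):
    offs = np.array([design.occasion_offset(k) for k in range(1, design.K + 1)])
    return offs, offs + np.asarray(design.Tks)


def capture_period_range(H: np.ndarray, design: StudyDesign):
    """First and last periods with a capture for each history row.

    Returns 1-based arrays ``(f, l)``; for the all-zero history ``f = K`` and
    ``l = 1`` so that every entry/departure window ``b <= d`` is feasible.
    """
    J = H.shape[0]
    K = design.K
    lo, hi = _period_bounds(design)
    any_in_period = np.empty((J, K), dtype=bool)
    for k in range(K):
        any_in_period[:, k] = H[:, lo[k]:hi[k]].any(axis=1)
    idx = np.arange(1, K + 1)
    f = np.where(any_in_period.any(axis=1),
                 np.where(any_in_period, idx, K + 1).min(axis=1), K)
    l = np.where(any_in_period.any(axis=1),
                 np.where(any_in_period, idx, 0).max(axis=1), 1)
    return f.astype(np.int64), l.astype(np.int64)


class HistoryWorkspace:
    """Precomputed, parameter-independent structure for probability evaluation.

    Caches the bit matrix (optionally a column subset), the first/last capture
    periods and, for every entry/departure window ``(b, d)``, the indices of
    the histories whose captures it covers.  Reused across many evaluations
    during optimization.
    """

    def __init__(self, design: StudyDesign, H: np.ndarray = None, columns=None):
        self.design = design
        if H is None:
            H = enumerate_histories(design)
        if columns is not None:
            columns = np.asarray(columns, dtype=np.int64)
            if columns.size == 0:
                raise ValueError("empty history subset")
            H = H[columns]
        self.H = H
        self.Hf = H.astype(float)
        self.n = H.shape[0]
        self.lo, self.hi = _period_bounds(design)
        f, l = capture_period_range(H, design)
        K = design.K
        self.pairs = []
        for b in range(1, K + 1):
            for d in range(b, K + 1):
                idx = np.flatnonzero((f >= b) & (l <= d))
                if idx.size:
                    self.pairs.append((b, d, idx))

    def prob(self, theta: ParameterSet, jacobian: bool = False):
        design = self.design
        theta.validate_against(design)
        K, T = design.K, design.T
        n, Hf = self.n, self.Hf
        p, phi, beta = theta.p, theta.phi, theta.beta
        logp = np.log(p)
        log1mp = np.log1p(-p)
        # per-period log Bernoulli products, cumulative over periods
        contrib = Hf * (logp - log1mp)[None, :] + log1mp[None, :]
        cl = np.empty((n, K + 1))
        cl[:, 0] = 0.0
        for k in range(K):
            cl[:, k + 1] = cl[:, k] + contrib[:, self.lo[k]:self.hi[k]].sum(axis=1)

        logbeta = np.log(beta)
        logphi = np.log(phi) if phi.size else np.empty(0)
        log1mphi = np.log1p(-phi) if phi.size else np.empty(0)
        cum_logphi = np.concatenate([[0.0], np.cumsum(logphi)])

        pi = np.zeros(n)
        dpi = np.zeros((n, T + (K - 1) + K)) if jacobian else None
        if jacobian:
            gp = (Hf - p[None, :]) / (p * (1.0 - p))[None, :]

        for b, d, idx in self.pairs:
            logw = (logbeta[b - 1]
                    + (cum_logphi[d - 1] - cum_logphi[b - 1])
                    + (log1mphi[d - 1] if d < K else 0.0))
            term = np.exp(logw + cl[idx, d] - cl[idx, b - 1])
            pi[idx] += term
            if jacobian:
                dpi[idx, T + (K - 1) + (b - 1)] += term / beta[b - 1]
                for k in range(b, d):
                    dpi[idx, T + (k - 1)] += term / phi[k - 1]
                if d < K:
                    dpi[idx, T + (d - 1)] -= term / (1.0 - phi[d - 1])
                tcol = term[:, None]
                for k in range(b, d + 1):
                    sl = slice(self.lo[k - 1], self.hi[k - 1])
                    dpi[idx, sl] += tcol * gp[idx, sl]
        return pi, dpi


def history_prob_vector(theta: ParameterSet, design: StudyDesign,
                        H: np.ndarray = None, columns=None,
                        jacobian: bool = False):
    """Cell probabilities ``pi_j`` (and optionally their Jacobian).

    Parameters
    ----------
    theta : ParameterSet
        Fully expanded natural parameters.
    H : ndarray, optional
        ``(J, T)`` bit matrix; enumerated from the design if omitted.
    columns : array-like of int, optional
        Restrict to these canonical history indices (the returned vector is
        then unnormalized over the subset).
    jacobian : bool
        Also return ``dpi/deta`` with ``eta = (p, phi, beta)`` concatenated,
        shape ``(n_hist, T + 2K - 1)``.

    Returns
    -------
    pi : ndarray
        Probabilities, one per (selected) history; sums to one over the full
        set.
    dpi : ndarray or None
    """
    ws = HistoryWorkspace(design, H=H, columns=columns)
    return ws.prob(theta, jacobian=jacobian)


def history_probability(omega, theta: ParameterSet, design: StudyDesign) -> float:
    """Probability of a single latent history (scalar convenience wrapper)."""
    bits = np.asarray(omega, dtype=np.uint8).reshape(1, -1)
    if bits.shape[1] != design.T:
        raise ValueError("history length does not match design")
    pi, _ = history_prob_vector(theta, design, H=bits)
    return float(pi[0])
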