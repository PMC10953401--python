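"""Model parameters and the unconstrained (working) reparameterization.

The natural parameters of the latent process are

* ``N`` -- superpopulation size (all individuals ever available for capture),
* ``p_kt`` -- capture probability on secondary occasion ``t`` of period ``k``,
* ``phi_k`` -- survival probability from period ``k`` to ``k + 1``,
* ``beta_k`` -- probability of first entering the population in period ``k``,
  with ``sum_k beta_k = 1``.

Optimization works on an unconstrained vector: ``log N``, logits of the free
capture and survival parameters (``logit S`` for monthly survival), and logits
of the conditional entry probabilities ``beta*_k = beta_k / (1 - beta_1 - ...
- beta_{k-1})`` for ``k < K`` (stick-breaking), which enforces the simplex
constraint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .design import ModelSpec, StudyDesign

_EPS = 1e-12


@dataclass
class ParameterSet:
    """Natural-scale parameters, fully expanded over occasions/intervals.

    ``p`` has length ``design.T``; ``phi`` has length ``K - 1``; ``beta``
    length ``K`` and sums to one.  All probabilities must lie strictly in
    (0, 1).
    """

    N: float
    p: np.ndarray
    phi: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float)) \
            if np.size(self.phi) else np.empty(0)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.N <= 0:
            raise ValueError("N must be positive")
        for name, arr in (("p", self.p), ("phi", self.phi)):
            if arr.size and (np.any(arr <= 0.0) or np.any(arr >= 1.0)):
                raise ValueError(f"{name} entries must lie strictly in (0, 1)")
        # beta_k = 1 is legitimate in the single-period design
        if np.any(self.beta <= 0.0) or np.any(self.beta > 1.0):
            raise ValueError("beta entries must lie in (0, 1]")
        if not np.isclose(self.beta.sum(), 1.0, atol=1e-8):
            raise ValueError("beta must sum to 1")

    def validate_against(self, design: StudyDesign):
        if self.p.size != design.T:
            raise ValueError("p must have one entry per secondary occasion")
        if self.phi.size != design.K - 1:
            raise ValueError("phi must have K - 1 entries")
        if self.beta.size != design.K:
            raise ValueError("beta must have K entries")
        return self


def beta_from_sticks(bstar: np.ndarray) -> np.ndarray:
    """Entry probabilities from conditional entry probabilities.

    ``beta_k = beta*_k * prod_{i<k} (1 - beta*_i)``; the last class takes the
    remaining stick so the simplex constraint holds exactly.
    """
    bstar = np.asarray(bstar, dtype=float)
    K = bstar.size + 1
    beta = np.empty(K)
    rem = 1.0
    for k in range(K - 1):
        beta[k] = bstar[k] * rem
        rem *= 1.0 - bstar[k]
    beta[K - 1] = rem
    return beta


def sticks_from_beta(beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    K = beta.size
    bstar = np.empty(K - 1)
    rem = 1.0
    for k in range(K - 1):
        bstar[k] = beta[k] / rem
        rem -= beta[k]
    return bstar


def _capture_expansion(spec: ModelSpec, design: StudyDesign) -> np.ndarray:
    """0/1 matrix mapping free capture parameters to the T occasions."""
    T = design.T
    if spec.capture == "t":
        return np.eye(T)
    E = np.zeros((T, spec.n_capture_params(design)))
    if spec.capture == "k":
        for k in range(1, design.K + 1):
            off = design.occasion_offset(k)
            E[off:off + design.Tks[k - 1], k - 1] = 1.0
    else:
        E[:, 0] = 1.0
    return E


def _free_capture_values(theta: ParameterSet, spec: ModelSpec,
                         design: StudyDesign) -> np.ndarray:
    if spec.capture == "t":
        return theta.p
    if spec.capture == "k":
        return np.array([theta.p[design.occasion_offset(k)]
                         for k in range(1, design.K + 1)])
    return theta.p[:1]


def _free_survival_values(theta: ParameterSet, spec: ModelSpec,
                          design: StudyDesign) -> np.ndarray:
    if design.K == 1:
        return np.empty(0)
    if spec.survival == "k":
        return theta.phi
    deltas = np.asarray(design.deltas) if spec.survival == "m" \
        else np.ones(design.K - 1)
    # recover monthly S from the first interval
    return np.array([theta.phi[0] ** (1.0 / deltas[0])])


def to_working(theta: ParameterSet, spec: ModelSpec,
               design: StudyDesign) -> np.ndarray:
    """Map natural parameters to the unconstrained working vector.

    Layout: ``[log N, capture logits, survival logits, logit beta*_{1..K-1}]``.
    """
    theta.validate_against(design)
    vals = np.concatenate([
        _free_capture_values(theta, spec, design),
        _free_survival_values(theta, spec, design),
        sticks_from_beta(theta.beta) if design.K > 1 else np.empty(0),
    ])
    if np.any(vals <= 0.0) or np.any(vals >= 1.0):
        raise ValueError("probabilities at 0 or 1 cannot be mapped to logits")
    return np.concatenate([[np.log(theta.N)], logit(vals)])


def from_working(w: np.ndarray, spec: ModelSpec,
                 design: StudyDesign) -> ParameterSet:
    """Inverse of :func:`to_working`, expanding structures to full length."""
    theta, _ = expand_parameters(w, spec, design, jacobian=False)
    return theta


def expand_parameters(w: np.ndarray, spec: ModelSpec, design: StudyDesign,
                      jacobian: bool = False):
    """Expand a working vector to a full :class:`ParameterSet`.

    Returns ``(theta, J)`` where ``J`` (if requested) is the Jacobian of the
    expanded natural vector ``eta = (p_1..p_T, phi_1..phi_{K-1},
    beta_1..beta_K)`` with respect to the working vector (``d eta / d w``,
    shape ``(T + 2K - 1, len(w))``).  ``dN/dw_0 = N`` is handled separately
    by callers.
    """
    w = np.asarray(w, dtype=float)
    K, T = design.K, design.T
    n_p = spec.n_capture_params(design)
    n_s = spec.n_survival_params(design)
    if w.size != 1 + n_p + n_s + (K - 1):
        raise ValueError(
            f"working vector has {w.size} entries; model {spec} on this design "
            f"needs {1 + n_p + n_s + (K - 1)}")
    N = np.exp(w[0])
    wp = w[1:1 + n_p]
    ws = w[1 + n_p:1 + n_p + n_s]
    wb = w[1 + n_p + n_s:]

    p_free = np.clip(expit(wp), _EPS, 1.0 - _EPS)
    Ep = _capture_expansion(spec, design)
    p_full = Ep @ p_free

    if K == 1:
        phi = np.empty(0)
        S = None
    elif spec.survival == "k":
        phi = np.clip(expit(ws), _EPS, 1.0 - _EPS)
        S = None
    else:
        deltas = np.asarray(design.deltas) if spec.survival == "m" \
            else np.ones(K - 1)
        S = float(np.clip(expit(ws[0]), _EPS, 1.0 - _EPS))
        phi = S ** deltas

    bstar = np.clip(expit(wb), _EPS, 1.0 - _EPS)
    beta = beta_from_sticks(bstar) if K > 1 else np.array([1.0])

    theta = ParameterSet(N=N, p=p_full, phi=phi, beta=beta)
    if not jacobian:
        return theta, None

    n_eta = T + (K - 1) + K
    J = np.zeros((n_eta, w.size))
    # capture block: dp_full/dwp = Ep diag(p(1-p))
    J[:T, 1:1 + n_p] = Ep * (p_free * (1.0 - p_free))[None, :]
    # survival block
    if K > 1:
        if spec.survival == "k":
            J[T:T + K - 1, 1 + n_p:1 + n_p + n_s] = np.diag(phi * (1.0 - phi))
        else:
            deltas = np.asarray(design.deltas) if spec.survival == "m" \
                else np.ones(K - 1)
            J[T:T + K - 1, 1 + n_p] = deltas * (S ** deltas) * (1.0 - S)
    # entry block: dbeta/d logit(beta*)
    if K > 1:
        db = np.zeros((K, K - 1))
        for k in range(K):
            for i in range(min(k, K - 1)):
                db[k, i] = -beta[k] / (1.0 - bstar[i])
            if k < K - 1:
                db[k, k] = beta[k] / bstar[k]
        J[T + K - 1:, 1 + n_p + n_s:] = db * (bstar * (1.0 - bstar))[None, :]
    return theta, J


def probability_mask(spec: ModelSpec, design: StudyDesign) -> np.ndarray:
    """Boolean mask of working coordinates that are probability logits.

    These are the coordinates the logit-normal penalty applies to; ``log N``
    is never penalized.
    """
    n = spec.n_free_params(design)
    mask = np.ones(n, dtype=bool)
    mask[0] = False
    return mask
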