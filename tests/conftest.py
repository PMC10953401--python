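"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written differently from the package code:
history probabilities by a naive per-history window sum with direct floating
products (no logs, no vectorization), and the exact pmf of the observed
counts by exhaustive enumeration of the latent solutions of ``T x = y``.
"""

from math import lgamma

import numpy as np
import pytest

from batchmark import ParameterSet, StudyDesign
from batchmark.matrices import enumerate_latent_solutions


def naive_history_probability(bits, theta, design):
    """Brute-force window sum over (entry b, departure d) pairs."""
    bits = list(int(b) for b in bits)
    K = design.K
    # period blocks
    blocks = []
    pos = 0
    for k in range(K):
        blocks.append(bits[pos:pos + design.Tks[k]])
        pos += design.Tks[k]
    cap_periods = [k for k in range(K) if any(blocks[k])]
    first = min(cap_periods) if cap_periods else K - 1
    last = max(cap_periods) if cap_periods else 0
    total = 0.0
    for b in range(0, first + 1):
        for d in range(max(b, last), K):
            prob = theta.beta[b]
            for k in range(b, d + 1):
                off = design.occasion_offset(k + 1)
                for t in range(design.Tks[k]):
                    pkt = theta.p[off + t]
                    prob *= pkt if blocks[k][t] else (1.0 - pkt)
            for k in range(b, d):
                prob *= theta.phi[k]
            if d < K - 1:
                prob *= 1.0 - theta.phi[d]
            total += prob
    return total


def exact_log_pmf(y, N, pi, T_mat):
    """log P(Y = y) by exhaustive enumeration of {x >= 0 : Tx = y, sum x = N}."""
    sols = enumerate_latent_solutions(T_mat, np.asarray(y, int), int(N))
    if not sols:
        return -np.inf
    logpi = np.log(np.maximum(pi, 1e-300))
    tot = -np.inf
    for x in sols:
        lp = lgamma(N + 1) - sum(lgamma(v + 1) for v in x) + float(x @ logpi)
        tot = np.logaddexp(tot, lp)
    return tot


def random_theta(design, rng, N=100.0):
    """A valid random parameter set for fuzz tests."""
    beta = rng.dirichlet(np.full(design.K, 2.0))
    beta = np.clip(beta, 0.02, None)
    beta /= beta.sum()
    return ParameterSet(
        N=N,
        p=rng.uniform(0.1, 0.9, size=design.T),
        phi=rng.uniform(0.2, 0.95, size=design.K - 1),
        beta=beta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_design():
    """K=2 with one occasion each: the smallest design with recaptures."""
    return StudyDesign(K=2, Tks=(1, 1))


@pytest.fixture
def small_design():
    return StudyDesign(K=3, Tks=(2, 2, 2))


@pytest.fixture
def small_theta():
    return ParameterSet(N=100.0, p=np.full(6, 0.4), phi=[0.8, 0.7],
                        beta=[0.2, 0.3, 0.5])
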