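import numpy as np
import pytest
from scipy.stats import binom, norm

from batchmark import ParameterSet, StudyDesign
from batchmark.histories import history_prob_vector
from batchmark.matrices import build_transform, forced_zero_reduction
from batchmark.saddlepoint import (aic, cgf, log_saddlepoint_density,
                                   loglik_gradient_pi_N, penalty,
                                   solve_saddlepoint)

from conftest import exact_log_pmf, random_theta

BIN_DESIGN = StudyDesign(K=1, Tks=(1,))
BIN_THETA = ParameterSet(N=10, p=[0.3], phi=[], beta=[1.0])


def _binomial_setup():
    pi, _ = history_prob_vector(BIN_THETA, BIN_DESIGN)
    tm = build_transform(BIN_DESIGN)
    return pi, tm.T_mat


class TestCGF:
    def test_zero_at_origin_for_full_set(self, small_design, small_theta):
        pi, _ = history_prob_vector(small_theta, small_design)
        tm = build_transform(small_design)
        L = tm.T_mat.shape[0]
        assert cgf(np.zeros(L), small_theta.N, pi, tm.T_mat) == pytest.approx(0.0, abs=1e-10)

    def test_gradient_at_origin_is_mean(self, small_design, small_theta):
        pi, _ = history_prob_vector(small_theta, small_design)
        tm = build_transform(small_design)
        L = tm.T_mat.shape[0]
        _, grad = cgf(np.zeros(L), small_theta.N, pi, tm.T_mat, order=1)
        np.testing.assert_allclose(grad,
                                   small_theta.N * (tm.T_mat @ pi), atol=1e-10)

    def test_derivatives_match_finite_differences(self, rng):
        d = StudyDesign(K=2, Tks=(1, 1))
        th = random_theta(d, rng, N=30)
        pi, _ = history_prob_vector(th, d)
        tm = build_transform(d)
        s = rng.normal(0, 0.5, tm.T_mat.shape[0])
        v, g, H = cgf(s, th.N, pi, tm.T_mat, order=2)
        eps = 1e-6
        for i in range(s.size):
            sp, sm = s.copy(), s.copy()
            sp[i] += eps
            sm[i] -= eps
            gn = (cgf(sp, th.N, pi, tm.T_mat) - cgf(sm, th.N, pi, tm.T_mat)) / (2 * eps)
            assert g[i] == pytest.approx(gn, rel=1e-6, abs=1e-6)
            _, g1 = cgf(sp, th.N, pi, tm.T_mat, order=1)
            _, g2 = cgf(sm, th.N, pi, tm.T_mat, order=1)
            np.testing.assert_allclose(H[i], (g1 - g2) / (2 * eps),
                                       rtol=1e-5, atol=1e-6)

    def test_all_zero_pi_rejected(self):
        tm = build_transform(BIN_DESIGN)
        with pytest.raises(Exception):
            cgf(np.zeros(1), 10.0, np.zeros(2), tm.T_mat)


class TestSolve:
    def test_shat_zero_at_expected_counts(self, small_design, small_theta):
        pi, _ = history_prob_vector(small_theta, small_design)
        tm = build_transform(small_design)
        y = small_theta.N * np.asarray(tm.T_mat @ pi)  # non-integer on purpose
        sol = solve_saddlepoint(y, small_theta.N, pi, tm.T_mat)
        assert sol.converged
        np.testing.assert_allclose(sol.s_hat, 0.0, atol=1e-7)

    def test_binomial_closed_form(self):
        pi, T_mat = _binomial_setup()
        for y in (2, 3, 5, 7):
            sol = solve_saddlepoint(np.array([float(y)]), 10.0, pi, T_mat)
            closed = np.log((y / (10 - y)) * ((1 - 0.3) / 0.3))
            assert sol.converged
            assert sol.s_hat[0] == pytest.approx(closed, abs=1e-7)

    def test_shat_monotone_in_y(self):
        pi, T_mat = _binomial_setup()
        shats = [solve_saddlepoint(np.array([float(y)]), 10.0, pi, T_mat).s_hat[0]
                 for y in (2, 3, 4, 5)]
        assert np.all(np.diff(shats) > 0)

    def test_residual_below_tolerance(self, small_design, small_theta, rng):
        pi, _ = history_prob_vector(small_theta, small_design)
        tm = build_transform(small_design)
        x = rng.multinomial(int(small_theta.N), pi)
        y = np.asarray(tm.T_mat @ x, dtype=float)
        keep = y > 0
        kept, _ = forced_zero_reduction(tm.T_mat, y)
        sol = solve_saddlepoint(y[keep], small_theta.N, pi[kept],
                                tm.T_mat[keep][:, kept])
        assert sol.converged
        assert sol.gradient_residual <= 1e-8 * max(1.0, y.max())


class TestDensity:
    def test_binomial_pmf(self):
        pi, T_mat = _binomial_setup()
        ll = log_saddlepoint_density(np.array([3.0]), 10.0, pi, T_mat)
        assert np.exp(ll) == pytest.approx(binom.pmf(3, 10, 0.3), rel=0.05)

    def test_tiny_latent_exact_pmf(self, tiny_design):
        """At N=15 with three observed counts the first-order approximation
        carries a smooth ~10% overestimate in the bulk of the support (it
        shrinks as O(1/N); see the decay test below)."""
        th = ParameterSet(N=15, p=[0.5, 0.45], phi=[0.8], beta=[0.6, 0.4])
        pi, _ = history_prob_vector(th, tiny_design)
        tm = build_transform(tiny_design)
        y = np.array([5.0, 4.0, 2.0])  # modal observed counts
        ll = log_saddlepoint_density(y, 15.0, pi, tm.T_mat)
        ex = exact_log_pmf(y, 15, pi, tm.T_mat)
        assert np.exp(ll - ex) == pytest.approx(1.0, abs=0.15)

    def test_error_decays_with_population_size(self):
        """First-order saddlepoint error is O(1/N): doubling N roughly halves
        the relative pmf error at the modal observed counts."""
        d = StudyDesign(K=1, Tks=(3,))
        errs = {}
        for N in (20, 40):
            th = ParameterSet(N=N, p=[0.5] * 3, phi=[], beta=[1.0])
            pi, _ = history_prob_vector(th, d)
            tm = build_transform(d)
            x = np.floor(N * pi).astype(int)
            rem = N - x.sum()
            order = np.argsort(-(N * pi - x))
            x[order[:rem]] += 1
            y = np.asarray(tm.T_mat @ x, dtype=float)
            ll = log_saddlepoint_density(y, float(N), pi, tm.T_mat)
            ex = exact_log_pmf(y, N, pi, tm.T_mat)
            errs[N] = abs(np.exp(ll - ex) - 1.0)
        assert errs[40] < 0.10
        assert errs[40] < 0.75 * errs[20]

    def test_invariant_to_column_permutation(self, tiny_design, rng):
        th = ParameterSet(N=15, p=[0.5, 0.45], phi=[0.8], beta=[0.6, 0.4])
        pi, _ = history_prob_vector(th, tiny_design)
        tm = build_transform(tiny_design)
        y = np.array([6.0, 4.0, 3.0])
        base = log_saddlepoint_density(y, 15.0, pi, tm.T_mat)
        perm = rng.permutation(4)
        permuted = log_saddlepoint_density(
            y, 15.0, pi[perm], tm.T_mat[:, perm])
        assert permuted == pytest.approx(base, abs=1e-8)

    def test_forced_zero_reduction_preserves_likelihood_ratio(self, tiny_design):
        """Dropping impossible histories (unnormalized pi retained) leaves the
        likelihood unchanged up to numerical noise, hence ratios between
        parameter values agree."""
        tm = build_transform(tiny_design)
        y = np.array([5.0, 0.0, 3.0])
        kept, dropped = forced_zero_reduction(tm.T_mat, y)
        assert dropped.size > 0
        rows = y > 0
        lls = {}
        for tag, th in {
            "a": ParameterSet(N=15, p=[0.5, 0.45], phi=[0.8], beta=[0.6, 0.4]),
            "b": ParameterSet(N=15, p=[0.4, 0.5], phi=[0.7], beta=[0.5, 0.5]),
        }.items():
            pi, _ = history_prob_vector(th, tiny_design)
            full = exact_log_pmf(y, 15, pi, tm.T_mat)
            red = log_saddlepoint_density(y[rows], 15.0, pi[kept],
                                          tm.T_mat[rows][:, kept])
            lls[tag] = (full, red)
        ratio_exact = lls["a"][0] - lls["b"][0]
        ratio_reduced = lls["a"][1] - lls["b"][1]
        assert ratio_reduced == pytest.approx(ratio_exact, abs=np.log(1.01))

    def test_gradient_wrt_pi_and_N(self, tiny_design, rng):
        th = ParameterSet(N=15, p=[0.5, 0.45], phi=[0.8], beta=[0.6, 0.4])
        pi, _ = history_prob_vector(th, tiny_design)
        tm = build_transform(tiny_design)
        y = np.array([6.0, 4.0, 3.0])
        sol = solve_saddlepoint(y, 15.0, pi, tm.T_mat)
        dl_dpi, dl_dN = loglik_gradient_pi_N(y, 15.0, pi, tm.T_mat, sol)
        eps = 1e-6
        for j in range(pi.size):
            pp, pm = pi.copy(), pi.copy()
            pp[j] += eps
            pm[j] -= eps
            num = (log_saddlepoint_density(y, 15.0, pp, tm.T_mat)
                   - log_saddlepoint_density(y, 15.0, pm, tm.T_mat)) / (2 * eps)
            assert dl_dpi[j] == pytest.approx(num, rel=1e-4, abs=1e-6)
        num_N = (log_saddlepoint_density(y, 15.0 + eps, pi, tm.T_mat)
                 - log_saddlepoint_density(y, 15.0 - eps, pi, tm.T_mat)) / (2 * eps)
        assert dl_dN == pytest.approx(num_N, rel=1e-5, abs=1e-7)


class TestPenaltyAndAIC:
    def test_zero_at_half(self):
        w = np.array([np.log(100), 0.0, 0.0, 0.0])
        mask = np.array([False, True, True, True])
        P, grad = penalty(w, mask, sigma_p=3.0)
        assert P == 0.0
        np.testing.assert_array_equal(grad, 0.0)

    def test_single_logit_contribution(self):
        w = np.array([np.log(10), 3.0])
        mask = np.array([False, True])
        P, _ = penalty(w, mask, sigma_p=3.0)
        assert P == pytest.approx(0.5)

    def test_N_never_penalized(self):
        w = np.array([np.log(1e6), 0.0])
        mask = np.array([False, True])
        assert penalty(w, mask)[0] == 0.0

    def test_prior_interval_mass(self):
        """logit(theta) ~ N(0, 3^2) puts ~95% prior mass on (0.003, 0.997)."""
        upper = np.log(0.997 / 0.003)
        mass = norm.cdf(upper / 3.0) - norm.cdf(-upper / 3.0)
        assert mass == pytest.approx(0.95, abs=0.005)

    def test_order_invariance(self, rng):
        w = rng.normal(0, 2, 8)
        mask = np.ones(8, bool)
        mask[0] = False
        perm = rng.permutation(8)
        assert penalty(w, mask)[0] == pytest.approx(
            penalty(w[perm], mask[perm])[0])

    def test_aic_arithmetic(self):
        assert aic(-500.0, 23) == 1046.0
        # nested models: difference decomposes into 2*dk - 2*dloglik
        assert aic(-500.0, 23) - aic(-495.0, 20) == pytest.approx(
            2 * 3 - 2 * (-500 - -495))
        with pytest.raises(ValueError):
            aic(np.nan, 3)
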