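"""Model and results objects for saddlepoint ML fitting of batch-mark data.

:class:`BatchMarkModel` bundles the observed counts, the study design, the
structure of capture/survival probabilities, the history-reduction pipeline
(forced-zero removal and optional prefiltering) and the penalization choice.
``fit()`` maximizes the (optionally penalized) saddlepoint log-likelihood over
the unconstrained working parameters with analytic gradients and returns a
:class:`BatchMarkResults` carrying estimates, Wald standard errors and
confidence intervals, AIC, and derived per-period abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.special
import scipy.optimize
import scipy.sparse as sp

from .design import ModelSpec, StudyDesign
from .histories import (HistoryWorkspace, enumerate_histories,
                        history_prob_vector)
from .matrices import (CountData, build_transform, count_index,
                       forced_zero_reduction, prefilter_histories)
from .parameters import (ParameterSet, expand_parameters, probability_mask,
                         to_working)
from .saddlepoint import (SaddlepointError, aic, log_saddlepoint_density,
                          loglik_gradient_pi_N, penalty, solve_saddlepoint)

_BIG = 1e10


def initial_values(data: CountData, design: StudyDesign, spec: ModelSpec,
                   p_init: float = None) -> np.ndarray:
    """Deterministic Manly-Parr-style starting values (working scale).

    Capture probabilities come from within-period recapture fractions (or the
    user-supplied constant ``p_init``); crude period abundances follow by
    inflating period captures; survival from consecutive-period recapture
    rates of already-marked cohorts (clipped to (0.05, 0.95)); entry
    probabilities from first-capture proportions floored at 0.01; and
    ``N_hat = max(entrants estimate, 1.1 * total marked)``.
    """
    if data.total_marked == 0:
        raise ValueError("cannot compute initial values from all-zero data")
    K = design.K
    m_index, n_index = count_index(design)
    m = {kt: v for kt, v in zip(m_index, data.m)}
    n = {kjt: v for kjt, v in zip(n_index, data.n)}

    # capture probability per period from within-period recapture fractions
    p_hat = np.empty(K)
    num_all = den_all = 0.0
    for k in range(1, K + 1):
        num = den = 0.0
        cum = 0.0
        for t in range(1, design.Tks[k - 1] + 1):
            if t >= 2:
                num += n.get((k, k, t), 0)
                den += cum
            cum += m[(k, t)]
        num_all += num
        den_all += den
        p_hat[k - 1] = num / den if den > 0 else np.nan
    pooled = num_all / den_all if den_all > 0 else 0.2
    p_hat = np.where(np.isnan(p_hat), max(pooled, 0.02), p_hat)
    if p_init is not None:
        p_hat = np.full(K, float(p_init))
    p_hat = np.clip(p_hat, 0.02, 0.8)

    # crude per-period abundance: captures / P(caught at least once in period)
    caps = np.zeros(K)
    pstar = np.zeros(K)
    for k in range(1, K + 1):
        caps[k - 1] = sum(m[(k, t)] for t in range(1, design.Tks[k - 1] + 1))
        caps[k - 1] += sum(v for (c, j, t), v in n.items() if j == k)
        pstar[k - 1] = 1.0 - (1.0 - p_hat[k - 1]) ** design.Tks[k - 1]
    N_tilde = np.maximum(caps / np.maximum(pstar, 1e-3), 1.0)

    # survival from recapture rates of previously marked cohorts
    phi_hat = np.full(max(K - 1, 0), 0.7)
    for k in range(1, K):
        seen_k = sum(v for (c, j, t), v in n.items() if j == k and c <= k)
        seen_k1 = sum(v for (c, j, t), v in n.items() if j == k + 1 and c <= k)
        marked_k = caps[k - 1]
        alive_k = seen_k / max(pstar[k - 1], 1e-3) + marked_k
        alive_k1 = seen_k1 / max(pstar[k], 1e-3)
        if alive_k > 0 and seen_k1 > 0:
            phi_hat[k - 1] = alive_k1 / alive_k
    phi_hat = np.clip(phi_hat, 0.05, 0.95)

    # entry proportional to first captures, floored
    first = np.array([sum(m[(k, t)] for t in range(1, design.Tks[k - 1] + 1))
                      for k in range(1, K + 1)], dtype=float)
    beta_hat = np.maximum(first / max(first.sum(), 1.0), 0.01)
    beta_hat /= beta_hat.sum()

    entrants = N_tilde[0] + sum(
        max(N_tilde[k] - phi_hat[k - 1] * N_tilde[k - 1], 0.0)
        for k in range(1, K))
    N_hat = max(entrants, 1.1 * data.total_marked)

    p_full = np.concatenate([np.full(design.Tks[k - 1], p_hat[k - 1])
                             for k in range(1, K + 1)])
    theta0 = ParameterSet(N=N_hat, p=p_full, phi=phi_hat, beta=beta_hat)
    return to_working(theta0, spec, design)


class BatchMarkModel:
    """Latent multinomial model for extended batch-mark count data.

    Parameters
    ----------
    data : CountData
        Observed marking and recapture counts.
    model : str or ModelSpec
        Capture/survival structure, e.g. ``"p(t)phi(k)"``.
    penalize : bool
        Subtract the logit-normal penalty from the log-likelihood.
    sigma_p : float
        Penalty scale (default 3).
    prefilter : float or None
        If set, retain only this fraction of the highest-probability latent
        histories (evaluated at the starting values), with feasibility
        safeguards.
    """

    def __init__(self, data: CountData, model="p(t)phi(k)",
                 penalize: bool = False, sigma_p: float = 3.0,
                 prefilter: float = None):
        self.data = data
        self.design = data.design
        self.spec = ModelSpec.parse(model)
        self.penalize = bool(penalize)
        self.sigma_p = float(sigma_p)
        self.prefilter = prefilter
        if prefilter is not None and not (0.0 < prefilter <= 1.0):
            raise ValueError("prefilter fraction must lie in (0, 1]")

        self._H = enumerate_histories(self.design)
        self._tm = build_transform(self.design, self._H)
        y = data.y
        kept, dropped = forced_zero_reduction(self._tm.T_mat, y)
        self._forced_dropped = dropped
        rows = np.flatnonzero(y > 0)
        self._rows = rows
        self._base_cols = kept
        self._y = y[rows].astype(float)
        self._pmask = probability_mask(self.spec, self.design)
        # set at fit time (prefilter needs starting values)
        self._set_columns(kept)

    def _set_columns(self, cols: np.ndarray):
        self._cols = cols
        self._T_red = sp.csr_matrix(self._tm.T_mat[self._rows][:, cols])
        self._Td = np.asarray(self._T_red.todense())
        self._ws = HistoryWorkspace(self.design, H=self._H, columns=cols)

    @property
    def n_free_params(self) -> int:
        return self.spec.n_free_params(self.design)

    def _apply_prefilter(self, w0: np.ndarray):
        theta0, _ = expand_parameters(w0, self.spec, self.design)
        pi0, _ = history_prob_vector(theta0, self.design, H=self._H,
                                     columns=self._base_cols)
        local = prefilter_histories(
            pi0, fraction=self.prefilter,
            always_keep=[int(np.flatnonzero(self._base_cols == 0)[0])]
            if 0 in self._base_cols else None,
            T_mat=self._tm.T_mat[self._rows][:, self._base_cols], y=self._y)
        self._set_columns(self._base_cols[local])

    def _objective(self, w, state):
        """Negative (penalized) loglik and its gradient on the working scale."""
        try:
            theta, Jchain = expand_parameters(w, self.spec, self.design,
                                              jacobian=True)
            pi, dpi = self._ws.prob(theta, jacobian=True)
            sol = solve_saddlepoint(self._y, theta.N, pi, self._T_red,
                                    s0=state.get("s"), T_dense=self._Td)
            if not sol.converged and state.get("s") is not None:
                sol = solve_saddlepoint(self._y, theta.N, pi, self._T_red,
                                        T_dense=self._Td)
            if not sol.converged:
                state["fails"] += 1
                return _BIG, np.zeros_like(w)
            state["s"] = sol.s_hat
            ll = log_saddlepoint_density(self._y, theta.N, pi, self._T_red,
                                         sol=sol)
            dl_dpi, dl_dN = loglik_gradient_pi_N(self._y, theta.N, pi,
                                                 self._T_red, sol,
                                                 T_dense=self._Td)
            grad = Jchain.T @ (dpi.T @ dl_dpi)
            grad[0] += dl_dN * theta.N
        except (SaddlepointError, np.linalg.LinAlgError, FloatingPointError):
            state["fails"] += 1
            return _BIG, np.zeros_like(w)
        if self.penalize:
            P, dP = penalty(w, self._pmask, self.sigma_p)
            return -(ll - P), -(grad - dP)
        return -ll, -grad

    def loglik(self, working: np.ndarray, penalized: bool = None) -> float:
        """(Penalized) saddlepoint log-likelihood at a working vector."""
        if penalized is None:
            penalized = self.penalize
        theta, _ = expand_parameters(working, self.spec, self.design)
        pi, _ = self._ws.prob(theta)
        ll = log_saddlepoint_density(self._y, theta.N, pi, self._T_red,
                                     max_iter=200)
        if penalized:
            ll -= penalty(working, self._pmask, self.sigma_p)[0]
        return ll

    def fit(self, start: np.ndarray = None, starts=None, p_init: float = None,
            maxiter: int = 500, gtol: float = 1e-6,
            compute_se: bool = True) -> "BatchMarkResults":
        """Maximize the (penalized) saddlepoint likelihood.

        ``starts`` may be a list of working vectors; by default a single
        Manly-Parr-style heuristic start is used (``p_init`` overrides its
        capture probabilities).  With several starts the best converged
        optimum is returned and all optima recorded.
        """
        if starts is None:
            if start is not None:
                starts = [np.asarray(start, float)]
            else:
                starts = [initial_values(self.data, self.design, self.spec,
                                         p_init=p_init)]
        if self.prefilter is not None:
            self._apply_prefilter(starts[0])

        attempts = []
        for w0 in starts:
            state = {"s": None, "fails": 0}
            res = scipy.optimize.minimize(
                self._objective, np.asarray(w0, float), args=(state,),
                jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14,
                         "maxls": 80,
                         # effectively full-memory at these dimensions; the
                         # likelihood is too ill-conditioned for the default
                         "maxcor": max(2 * w0.size, 10)})
            x, fval, gmax, hess = self._newton_polish(res.x, state)
            ok = bool(np.isfinite(fval) and fval < _BIG / 2)
            attempts.append({"w": x, "objective": float(fval),
                             "converged": ok, "nit": int(res.nit),
                             "grad_max": gmax, "hessian": hess,
                             "inner_failures": state["fails"],
                             "message": str(res.message)})
        good = [a for a in attempts if a["converged"]]
        if not good:
            raise RuntimeError(
                "no start converged: " + "; ".join(a["message"] for a in attempts))
        best = min(good, key=lambda a: a["objective"])
        return self._build_results(best["w"], attempts, hessian=best["hessian"],
                                   compute_se=compute_se)

    def _newton_polish(self, x, state, gtol_polish: float = 1e-4,
                       max_rounds: int = 3, max_steps: int = 40):
        """Polish an L-BFGS optimum with damped fixed-Hessian Newton steps.

        L-BFGS tends to stall in the ill-conditioned valleys this likelihood
        produces (curvatures span several orders of magnitude); a few Newton
        steps with the observed-information matrix fix that cheaply.  Returns
        the polished point, objective, gradient norm and the last Hessian
        (reused for Wald inference when still current).
        """
        f, g = self._objective(x, state)
        hess = None
        for _ in range(max_rounds):
            gmax = float(np.max(np.abs(g)))
            if gmax <= gtol_polish or f >= _BIG / 2:
                break
            hess = self._hessian_working(x, state)
            try:
                c = scipy.linalg.cho_factor(
                    hess + 1e-8 * np.eye(hess.shape[0]), lower=True)
            except np.linalg.LinAlgError:
                break
            moved = False
            for _ in range(max_steps):
                gmax = float(np.max(np.abs(g)))
                if gmax <= gtol_polish:
                    break
                step = -scipy.linalg.cho_solve(c, g)
                alpha, ok = 1.0, False
                gd = g @ step
                if gd >= 0:  # not a descent direction for this Hessian
                    break
                for _ in range(30):
                    f_new, g_new = self._objective(x + alpha * step, state)
                    if f_new <= f + 1e-4 * alpha * gd:
                        ok = True
                        break
                    alpha *= 0.5
                if not ok:
                    break
                x = x + alpha * step
                f, g = f_new, g_new
                moved = True
            if not moved:
                break
        return x, f, float(np.max(np.abs(g))), hess

    # -- inference -----------------------------------------------------------

    def _hessian_working(self, w_hat: np.ndarray, state=None) -> np.ndarray:
        """Observed information: FD of the analytic gradient (central)."""
        n = w_hat.size
        Hm = np.empty((n, n))
        if state is None:
            state = {"s": None, "fails": 0}
            self._objective(w_hat, state)  # warm-start the inner solve
        for i in range(n):
            h = 1e-5 * max(1.0, abs(w_hat[i]))
            wp, wm = w_hat.copy(), w_hat.copy()
            wp[i] += h
            wm[i] -= h
            _, gp = self._objective(wp, state)
            _, gm = self._objective(wm, state)
            Hm[i] = (gp - gm) / (2.0 * h)
        return 0.5 * (Hm + Hm.T)

    def _covariance(self, w_hat: np.ndarray, Hm: np.ndarray = None):
        if Hm is None:
            Hm = self._hessian_working(w_hat)
        ridged = False
        for ridge in (0.0, 1e-8, 1e-6, 1e-4):
            try:
                c = np.linalg.cholesky(Hm + ridge * np.eye(Hm.shape[0]))
                cov = np.linalg.inv(Hm + ridge * np.eye(Hm.shape[0]))
                ridged = ridge > 0
                return cov, ridged, True
            except np.linalg.LinAlgError:
                continue
        return np.full_like(Hm, np.nan), False, False

    def _build_results(self, w_hat: np.ndarray, attempts,
                       hessian: np.ndarray = None,
                       compute_se: bool = True) -> "BatchMarkResults":
        theta, Jchain = expand_parameters(w_hat, self.spec, self.design,
                                          jacobian=True)
        ll_unpen = self.loglik(w_hat, penalized=False)
        P, _ = penalty(w_hat, self._pmask, self.sigma_p)
        ll_pen = ll_unpen - P
        ll_used = ll_pen if self.penalize else ll_unpen
        if compute_se:
            cov_w, ridged, se_ok = self._covariance(w_hat, Hm=hessian)
        else:
            n = w_hat.size
            cov_w, ridged, se_ok = np.full((n, n), np.nan), False, False
        return BatchMarkResults(
            model=self, working=w_hat, theta=theta, chain_jacobian=Jchain,
            cov_working=cov_w, se_available=se_ok,
            loglik=ll_unpen, penalty_value=P, penalized_loglik=ll_pen,
            aic=aic(ll_used, self.n_free_params),
            diagnostics={"attempts": attempts, "hessian_ridged": ridged,
                         "n_histories": int(self._cols.size),
                         "forced_zero_dropped": int(self._forced_dropped.size),
                         "prefilter": self.prefilter})


@dataclass
class BatchMarkResults:
    """Fit results: estimates, uncertainties and model-selection quantities."""

    model: BatchMarkModel
    working: np.ndarray
    theta: ParameterSet
    chain_jacobian: np.ndarray
    cov_working: np.ndarray
    se_available: bool
    loglik: float
    penalty_value: float
    penalized_loglik: float
    aic: float
    diagnostics: dict = field(default_factory=dict)

    # -- parameter table -----------------------------------------------------

    def _natural_names(self):
        design = self.model.design
        names = ["N"]
        names += [f"phi_{k}" for k in range(1, design.K)]
        names += [f"beta_{k}" for k in range(1, design.K + 1)]
        names += [f"p_{k}{t}" for (k, t) in design.occasions]
        return names

    def params_table(self) -> pd.DataFrame:
        """Point estimates, delta-method SEs and 95% Wald CIs.

        CIs are built on a transformed scale (log for ``N``, logit for
        probabilities) and back-transformed, so they respect the natural
        ranges.
        """
        design = self.model.design
        T, K = design.T, design.K
        theta = self.theta
        eta = np.concatenate([theta.p, theta.phi, theta.beta])
        cov = self.cov_working
        z = 1.96

        rows = []
        # N on the log scale: working coordinate 0 is log N
        se_logN = np.sqrt(cov[0, 0]) if self.se_available else np.nan
        rows.append(("N", theta.N, theta.N * se_logN,
                     theta.N * np.exp(-z * se_logN),
                     theta.N * np.exp(z * se_logN)))
        if self.se_available:
            cov_eta = self.chain_jacobian @ cov @ self.chain_jacobian.T
            se_eta = np.sqrt(np.clip(np.diag(cov_eta), 0.0, None))
        else:
            se_eta = np.full(eta.size, np.nan)
        order = ([T + i for i in range(K - 1)]              # phi
                 + [T + K - 1 + i for i in range(K)]        # beta
                 + list(range(T)))                          # p
        names = self._natural_names()[1:]
        for name, i in zip(names, order):
            est, se = eta[i], se_eta[i]
            if np.isfinite(se) and se > 0:
                se_logit = se / (est * (1.0 - est))
                lo = float(_expit(_logit(est) - z * se_logit))
                hi = float(_expit(_logit(est) + z * se_logit))
            elif se == 0:
                lo = hi = est
            else:
                lo, hi = np.nan, np.nan
            rows.append((name, est, se, lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se",
                                           "lcl", "ucl"])

    def derived_abundance(self) -> pd.DataFrame:
        """Expected per-period abundances ``N_k = N * psi_k`` with log-scale CIs.

        ``psi_1 = beta_1``; ``psi_{k+1} = psi_k phi_k + beta_{k+1}`` (the
        fraction of the superpopulation present in period ``k``).
        """
        design = self.model.design
        z = 1.96
        Nk = derived_abundance(self.theta, design)
        rows = []
        for k in range(design.K):
            if self.se_available:
                g = _fd_gradient(
                    lambda w, kk=k: np.log(derived_abundance(
                        expand_parameters(w, self.model.spec, design)[0],
                        design)[kk]),
                    self.working)
                se_log = float(np.sqrt(max(g @ self.cov_working @ g, 0.0)))
                se = Nk[k] * se_log
                lo, hi = Nk[k] * np.exp(-z * se_log), Nk[k] * np.exp(z * se_log)
            else:
                se = lo = hi = np.nan
            rows.append((f"N_{k + 1}", Nk[k], se, lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se",
                                           "lcl", "ucl"])

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        lines = [
            "Latent multinomial batch-mark model (saddlepoint ML)",
            f"  model: {m.spec}   design: K={m.design.K}, T={m.design.T}",
            f"  likelihood: {'penalized (sigma_p=%g)' % m.sigma_p if m.penalize else 'original'}"
            + (f", prefilter={m.prefilter}" if m.prefilter else ""),
            f"  latent histories retained: {self.diagnostics.get('n_histories')}"
            f" (forced-zero dropped: {self.diagnostics.get('forced_zero_dropped')})",
            f"  loglik: {self.loglik:.4f}   penalized: {self.penalized_loglik:.4f}"
            f"   AIC: {self.aic:.2f}   k: {m.n_free_params}",
            "",
            self.params_table().to_string(index=False, float_format="%.4f"),
            "",
            self.derived_abundance().to_string(index=False, float_format="%.2f"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        pt = self.params_table()
        da = self.derived_abundance()
        return {
            "model": str(self.model.spec),
            "penalized": self.model.penalize,
            "prefilter": self.model.prefilter,
            "loglik": self.loglik,
            "penalized_loglik": self.penalized_loglik,
            "aic": self.aic,
            "n_free_params": self.model.n_free_params,
            "parameters": pt.to_dict(orient="records"),
            "derived_abundance": da.to_dict(orient="records"),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if k != "attempts"},
        }


def derived_abundance(theta: ParameterSet, design: StudyDesign) -> np.ndarray:
    """Per-period expected abundances from the entry/survival recursion."""
    K = design.K
    psi = np.empty(K)
    psi[0] = theta.beta[0]
    for k in range(1, K):
        psi[k] = psi[k - 1] * theta.phi[k - 1] + theta.beta[k]
    return theta.N * psi


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(x):
    return scipy.special.expit(x)


def _fd_gradient(f, x, h: float = 1e-6):
    g = np.empty(x.size)
    for i in range(x.size):
        hp = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += hp
        xm[i] -= hp
        g[i] = (f(xp) - f(xm)) / (2.0 * hp)
    return g


def default_starts(data: CountData, design: StudyDesign, spec: ModelSpec,
                   multi: bool = True):
    """Heuristic start plus the diffuse ``p = 0.10`` and ``p = 0.40`` variants."""
    starts = [initial_values(data, design, spec)]
    if multi:
        starts.append(initial_values(data, design, spec, p_init=0.10))
        starts.append(initial_values(data, design, spec, p_init=0.40))
    return starts


def compare_models(data: CountData, models, penalize: bool = False,
                   sigma_p: float = 3.0, prefilter: float = None,
                   **fit_kwargs) -> pd.DataFrame:
    """Fit several model structures and rank them by AIC.

    Returns one row per model with loglik, parameter count, AIC and delta-AIC
    (ascending).  Models whose fit fails are flagged and excluded from the
    ranking.
    """
    models = list(models)
    if len(models) < 1:
        raise ValueError("need at least one model")
    rows = []
    for mstr in models:
        spec = ModelSpec.parse(mstr)
        try:
            fit = BatchMarkModel(data, model=spec, penalize=penalize,
                                 sigma_p=sigma_p, prefilter=prefilter
                                 ).fit(**fit_kwargs)
            rows.append({"model": str(spec), "loglik": fit.loglik,
                         "penalized_loglik": fit.penalized_loglik,
                         "n_params": fit.model.n_free_params,
                         "aic": fit.aic, "converged": True})
        except (RuntimeError, SaddlepointError, np.linalg.LinAlgError) as exc:
            rows.append({"model": str(spec), "loglik": np.nan,
                         "penalized_loglik": np.nan,
                         "n_params": spec.n_free_params(data.design),
                         "aic": np.nan, "converged": False,
                         "error": str(exc)})
    df = pd.DataFrame(rows)
    best = df.loc[df["converged"], "aic"].min()
    df["delta_aic"] = df["aic"] - best
    return df.sort_values("aic", na_position="last").reset_index(drop=True)
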