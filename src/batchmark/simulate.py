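"""Simulation of batch-mark datasets and replicated study harnesses.

``simulate_dataset`` draws latent history counts ``x ~ Multinomial(N, pi)``
and aggregates them to observed counts ``y = T x``.  The study harnesses
replicate the simulate/fit cycle and summarize estimator performance (mean,
RMSE, CI coverage and width per parameter) or AIC-based model selection
counts.

``REFERENCE_TRUTH`` holds the generating parameters of the package's reference
simulation regime: K = 6 primary periods of 2 secondary occasions, N = 5000,
beta = (0.10, 0.24, 0.11, 0.12, 0.18, 0.25), phi = (0.87, 0.82, 0.93, 0.54,
0.52) and per-occasion capture probabilities between 0.13 and 0.40.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelSpec, StudyDesign
from .histories import enumerate_histories, history_prob_vector
from .matrices import CountData, build_transform
from .model import BatchMarkModel, derived_abundance, initial_values
from .parameters import ParameterSet

REFERENCE_DESIGN = StudyDesign(K=6, Tks=(2, 2, 2, 2, 2, 2))

REFERENCE_TRUTH = ParameterSet(
    N=5000.0,
    beta=np.array([0.10, 0.24, 0.11, 0.12, 0.18, 0.25]),
    phi=np.array([0.87, 0.82, 0.93, 0.54, 0.52]),
    p=np.array([0.27, 0.22, 0.25, 0.21, 0.17, 0.29,
                0.33, 0.13, 0.19, 0.40, 0.14, 0.26]),
)


def draw_generating_parameters(design: StudyDesign, N: float,
                               rng: np.random.Generator) -> ParameterSet:
    """Draw a random generating parameter set for simulation regimes.

    Entry probabilities come from a Multinomial(100, 1/K)/100 draw (zeros
    redrawn), survival from Uniform(0.5, 0.95) and capture from
    Uniform(0.1, 0.4).
    """
    K = design.K
    while True:
        counts = rng.multinomial(100, np.full(K, 1.0 / K))
        if np.all(counts > 0):
            break
    return ParameterSet(
        N=N,
        beta=counts / 100.0,
        phi=rng.uniform(0.5, 0.95, size=K - 1),
        p=rng.uniform(0.1, 0.4, size=design.T),
    )


def simulate_dataset(theta: ParameterSet, design: StudyDesign, seed,
                     return_latent: bool = False):
    """Simulate one batch-mark dataset from the latent multinomial process."""
    theta.validate_against(design)
    rng = np.random.default_rng(seed)
    H = enumerate_histories(design)
    pi, _ = history_prob_vector(theta, design, H=H)
    x = rng.multinomial(int(round(theta.N)), pi / pi.sum())
    tm = build_transform(design, H)
    y = np.asarray(tm.T_mat @ x).ravel()
    m_len = tm.A.shape[0]
    data = CountData(design=design, m=y[:m_len], n=y[m_len:])
    if return_latent:
        return data, x
    return data


@dataclass
class SimulationConfig:
    """Settings for a replicated simulation study."""

    design: StudyDesign
    theta: ParameterSet
    n_replicates: int = 30
    seed: int = 0
    model: str = "p(t)phi(k)"
    run_penalized: bool = True
    sigma_p: float = 3.0
    prefilter: float = None
    models: list = field(default_factory=list)  # for selection studies
    max_failure_fraction: float = 0.2


def _true_values(theta: ParameterSet, design: StudyDesign) -> dict:
    vals = {"N": theta.N}
    vals.update({f"phi_{k + 1}": theta.phi[k] for k in range(design.K - 1)})
    vals.update({f"beta_{k + 1}": theta.beta[k] for k in range(design.K)})
    vals.update({f"p_{k}{t}": theta.p[design.occasion_offset(k) + t - 1]
                 for (k, t) in design.occasions})
    for k, nk in enumerate(derived_abundance(theta, design)):
        vals[f"N_{k + 1}"] = nk
    return vals


def _replicate_seeds(seed, n):
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def _fit_one(data, model, penalize, sigma_p, prefilter, start=None,
             compute_se=True):
    bm = BatchMarkModel(data, model=model, penalize=penalize,
                        sigma_p=sigma_p, prefilter=prefilter)
    return bm.fit(start=start, compute_se=compute_se)


def _collect(fit):
    tab = pd.concat([fit.params_table(), fit.derived_abundance()],
                    ignore_index=True)
    return tab.set_index("parameter")


def run_simulation_study(config: SimulationConfig) -> "StudySummary":
    """Replicated simulate-and-fit study (parameter-recovery summary).

    Fits the configured model with the original likelihood and, when
    ``run_penalized`` is set, refits each replicate with the penalized
    likelihood warm-started from the unpenalized optimum.  Non-converged
    replicates are excluded and counted; the study aborts if more than
    ``max_failure_fraction`` fail.
    """
    design, theta = config.design, config.theta
    truths = _true_values(theta, design)
    seeds = _replicate_seeds(config.seed, config.n_replicates)
    records = {"original": [], "penalized": []}
    failures = 0
    for r, s in enumerate(seeds):
        data = simulate_dataset(theta, design, seed=int(s))
        try:
            fit = _fit_one(data, config.model, False, config.sigma_p,
                           config.prefilter)
            records["original"].append(_collect(fit))
            if config.run_penalized:
                pfit = _fit_one(data, config.model, True, config.sigma_p,
                                config.prefilter, start=fit.working)
                records["penalized"].append(_collect(pfit))
        except (RuntimeError, np.linalg.LinAlgError):
            failures += 1
            continue
    n_ok = len(records["original"])
    if n_ok == 0 or failures / config.n_replicates > config.max_failure_fraction:
        raise RuntimeError(
            f"simulation study failed: {failures}/{config.n_replicates} "
            f"replicates did not converge")

    variants = ["original"] + (["penalized"] if config.run_penalized else [])
    tables = {}
    estimates = {}
    for variant in variants:
        rows = []
        reps = records[variant]
        est_df = pd.DataFrame({p: [t.loc[p, "estimate"] for t in reps]
                               for p in truths})
        estimates[variant] = est_df
        for pname, true in truths.items():
            est = est_df[pname].to_numpy()
            lcl = np.array([t.loc[pname, "lcl"] for t in reps])
            ucl = np.array([t.loc[pname, "ucl"] for t in reps])
            ok = np.isfinite(lcl) & np.isfinite(ucl)
            cover = np.mean((lcl[ok] <= true) & (true <= ucl[ok])) * 100 \
                if ok.any() else np.nan
            width = np.mean(ucl[ok] - lcl[ok]) if ok.any() else np.nan
            rows.append({"parameter": pname, "true": true,
                         "mean": est.mean(),
                         "rmse": float(np.sqrt(np.mean((est - true) ** 2))),
                         "cic": cover, "ciw": width})
        tables[variant] = pd.DataFrame(rows)
    return StudySummary(config=config, tables=tables, estimates=estimates,
                        n_converged=n_ok, n_failures=failures)


@dataclass
class StudySummary:
    """Per-parameter estimator performance over study replicates."""

    config: SimulationConfig
    tables: dict
    estimates: dict
    n_converged: int
    n_failures: int

    def table(self, variant: str = "original") -> pd.DataFrame:
        return self.tables[variant]

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: Parameter, True, then Mean/RMSE/CIC%/CIW per variant."""
        out = None
        for variant, tab in self.tables.items():
            t = tab.rename(columns={
                "mean": f"Mean_{variant}", "rmse": f"RMSE_{variant}",
                "cic": f"CIC%_{variant}", "ciw": f"CIW_{variant}",
                "parameter": "Parameter", "true": "True"})
            out = t if out is None else out.merge(
                t, on=["Parameter", "True"], how="outer")
        return out


def run_selection_study(config: SimulationConfig) -> pd.DataFrame:
    """AIC model-selection study over a list of candidate structures.

    For each replicate every candidate model is fitted with the original
    likelihood and (when ``run_penalized``) the penalized likelihood;
    the minimum-AIC model is recorded.  Returns a table of selection counts
    per model and likelihood variant.
    """
    if not config.models:
        raise ValueError("config.models must list candidate model structures")
    models = [str(ModelSpec.parse(m)) for m in config.models]
    design, theta = config.design, config.theta
    seeds = _replicate_seeds(config.seed, config.n_replicates)
    counts = {"original": {m: 0 for m in models},
              "penalized": {m: 0 for m in models}}
    n_ok = 0
    failures = 0
    for r, s in enumerate(seeds):
        data = simulate_dataset(theta, design, seed=int(s))
        try:
            aic_orig, aic_pen = {}, {}
            for m in models:
                # AIC ranking does not need the Wald covariance
                fit = _fit_one(data, m, False, config.sigma_p,
                               config.prefilter, compute_se=False)
                aic_orig[m] = fit.aic
                if config.run_penalized:
                    pfit = _fit_one(data, m, True, config.sigma_p,
                                    config.prefilter, start=fit.working,
                                    compute_se=False)
                    aic_pen[m] = pfit.aic
        except (RuntimeError, np.linalg.LinAlgError):
            failures += 1
            continue
        n_ok += 1
        counts["original"][min(aic_orig, key=aic_orig.get)] += 1
        if config.run_penalized:
            counts["penalized"][min(aic_pen, key=aic_pen.get)] += 1
    if n_ok == 0 or failures / config.n_replicates > config.max_failure_fraction:
        raise RuntimeError(
            f"selection study failed: {failures}/{config.n_replicates} "
            f"replicates did not converge")
    rows = []
    variants = ["original"] + (["penalized"] if config.run_penalized else [])
    for variant in variants:
        row = {"likelihood": variant, "n_replicates": n_ok}
        row.update(counts[variant])
        rows.append(row)
    return pd.DataFrame(rows)
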