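# Methods

## Latent process

The study design is a robust design with `K` primary periods, period `k`
holding `T_k` secondary occasions (`T = Σ T_k` occasions in total). The
population is closed within a primary period and open between periods;
recruitment happens at the start of a period and emigration/death is
permanent. Parameters:

| symbol | meaning | count | default scale |
|---|---|---|---|
| `N` | superpopulation size | 1 | `log N` |
| `p_kt` | capture probability, occasion `(k,t)` | per structure | logit |
| `φ_k` | survival over interval `k → k+1` | `K−1` or 1 | logit (`logit S` for monthly) |
| `β_k` | entry probability of period `k` | `K−1` free | logit of stick-breaking `β*_k` |

A latent capture history `ω ∈ {0,1}^T` is indexed canonically by the integer
whose binary expansion (most significant bit first) equals `ω` read
period-major/occasion-minor; this fixes the column order of every matrix. Its
probability is computed as a sum over entry period `b` and departure period
`d` covering all captures:

```
π_ω = Σ_{b ≤ f(ω)} Σ_{d ≥ l(ω)} β_b · Π_{k=b..d} Π_t p_kt^{ω_kt}(1−p_kt)^{1−ω_kt}
        · Π_{k=b..d−1} φ_k · (1−φ_d  if d < K)
```

with `f`/`l` the first/last periods containing a capture (the never-captured
history sums over every `b ≤ d`). This direct window sum — at most
`K(K+1)/2` vectorized terms over all histories — was chosen over a forward
recursion because it exposes the per-window terms that the analytic Jacobian
`∂π/∂(p, φ, β)` reuses; a naive per-history oracle in the test suite checks
equivalence to 1e-12.

The stick-breaking entry parameterization (`β*_1 = β_1`,
`β*_k = β_k / (1 − β_1 − … − β_{k−1})`) makes the simplex constraint
automatic; `β_K` is recovered by the recursion, never by subtracting rounded
values, so `Σβ_k = 1` holds to machine precision. The constant-survival
structure `φ(·)` is implemented as the monthly structure `φ(m)` with unit
spacing (`φ_k = S^{Δ_k}`, all `Δ_k = 1`), giving one code path for both.

## Observed counts and reduction

Counts are indexed `m_(k,t)` (first markings, period-major) followed by
`n_(k,j,t)` (recaptures of cohort `k` on occasion `(j,t)`), lexicographic,
with the structural zeros (`j < k`; `j = k, t = 1`) removed. `A`, `B` and
`T = (A′,B′)′` are stored sparse (CSR); a dense copy of the reduced `T` is
kept for the inner linear algebra, which at these sizes is faster through
BLAS than through sparse kernels.

**Forced-zero reduction.** Any history with a 1 in a row where `y_l = 0` is
removed (single pass; sufficient for 0/1 matrices and nonnegative counts).
The remaining `π` is used **unnormalized**: the missing mass enters the CGF
through `K(0) = N log Σ_retained π < 0` and is exactly the probability that
all removed categories are empty, so the likelihood of the observed data is
unchanged (property-tested against exhaustive enumeration). After column
removal the zero rows of `T` are identically zero and are dropped too —
otherwise `K″` would be singular in those coordinates.

**Prefiltering.** Optionally only the `⌈fraction·J⌉` histories with the
highest probability at the starting values are retained (ties broken by
canonical index), always including the never-captured history. Because an
arbitrary cut can make `Tx = y` infeasible, dropped histories are re-added
greedily in probability order until an LP feasibility check passes. This
mirrors how one trades a small likelihood distortion for a large memory
saving on big designs; on the desk-scale problems in this repository it is
exercised by tests but not needed.

## Saddlepoint likelihood

`M_Y(s) = M_X(T′s)` for `Y = TX`, so
`K_Y(s) = N log Σ_j π_j e^{(T′s)_j}` (evaluated with log-sum-exp shifting).
The approximate log-likelihood is

```
log f̃(y) = −(L/2) log 2π − ½ log|K″_Y(ŝ)| + K_Y(ŝ) − ŝ′y.
```

**Inner solve.** `ŝ` minimizes the convex `K_Y(s) − s′y` by Newton with
Cholesky solves and trust-region damping (initial radius 1, grow ×2.5 on
well-predicted clipped steps, shrink ×¼ on rejection). Plain backtracking was
abandoned: far from the optimum the CGF is so non-quadratic that Armijo
needed dozens of halvings per step. Convergence is declared at
`‖K′(ŝ) − y‖_∞ ≤ 1e-8 · max(1, max y)` — the relative form matters because
with counts of order 10³ an absolute 1e-8 sits at the float64 noise floor of
the log-sum-exp. Steps whose predicted reduction falls below
`1e-10(|f|+1)` are taken blindly when tiny (the ratio test is meaningless in
noise). Warm starts from the previous outer iterate cut the typical solve to
a few iterations; a failed warm solve is retried cold. The log-determinant
uses the Cholesky factor, with a single 1e-10-ridged retry.

**Outer derivatives.** Gradients of the log-likelihood with respect to the
working parameters are fully analytic: the envelope identity removes
`∂ŝ/∂θ` from `K(ŝ) − ŝ′y`, while the log-det term needs the third cumulant,

```
t_l = tr(G ∂K″/∂s_l),  G = K″(ŝ)^{-1},
dℓ/dπ_j = N r_j [1 − ½(d_j − tr(GM) − 2g1_j + 2μ′Gμ) + ½(g2_j − v′μ)],
dℓ/dN  = log S0 − L/(2N) + ½ v′μ,
```

with `r = e^{T′ŝ}/S0`, `d_j = T_j′ G T_j`, `g1 = T′Gμ`, `v = Gt`,
`g2 = T′v`. These contract into the analytic Jacobian `∂π/∂η` and the
chain rule of the working transform. Central finite differences verify the
whole gradient to ~1e-6 relative in the tests. (An AD tool would give the
same derivatives; hand-deriving them keeps the package dependency-light and
is exact.)

**Outer optimization.** L-BFGS-B on the unconstrained working vector,
followed by a damped Newton "polish" using the observed information (finite
differences of the analytic gradient): the likelihood's curvature spans
several orders of magnitude across coordinates and L-BFGS reliably stalls on
its relative-reduction test in the flat survival valleys. The polish Hessian
is reused for Wald inference. Inner-solve failures during line search return
a large finite objective (step rejected), not a fit failure. Default: single
deterministic start; the CLI `fit` adds the diffuse `p = 0.10` and
`p = 0.40` variants.

**Starting values.** A deterministic Manly–Parr-flavoured heuristic:
per-period capture probabilities from within-period recapture fractions
(clipped to (0.02, 0.8)); crude period abundances by inflating period
captures by the probability of being caught at least once; survival from
recapture rates of already-marked cohorts in consecutive periods (clipped to
(0.05, 0.95), 0.7 fallback); entry proportional to first captures floored at
0.01; `N̂ = max(entrants estimate, 1.1 × total marked)`. It only needs to
land in the basin of attraction; the multi-start option covers pathological
data.

**Penalty.** `P = Σ w²/(2σ_p²)` over the probability-type working
coordinates (capture, survival, conditional-entry logits — never `log N`),
default `σ_p = 3`, i.e. independent `N(0, 9)` priors on the logits putting
≈95% mass on (0.003, 0.997). AIC under penalization uses the penalized
optimum's objective value; the unpenalized log-likelihood at the same point
is also reported.

**Inference.** SEs on the working scale from the inverse observed
information (ridge-escalated Cholesky 0 → 1e-4; failure flags SEs
unavailable rather than silently degrading). 95% CIs are built on the
working scale and back-transformed — log scale for `N` and the derived
`N_k`, logit scale (delta-method SE of the logit) for every probability — so
intervals always respect the natural range. Derived abundances use
`ψ_1 = β_1`, `ψ_{k+1} = ψ_k φ_k + β_{k+1}`, `N_k = N ψ_k`.

## Simulator and study harness

`simulate_dataset` draws `x ~ Multinomial(N, π)` over all `2^T` histories
and returns `y = Tx`; with `return_latent=True` it exposes `x` for
moment-identity tests. The reference regimes are K=6 periods × 2 occasions
with `β = (0.10, 0.24, 0.11, 0.12, 0.18, 0.25)`,
`φ = (0.87, 0.82, 0.93, 0.54, 0.52)`,
`p = (0.27, 0.22, 0.25, 0.21, 0.17, 0.29, 0.33, 0.13, 0.19, 0.40, 0.14,
0.26)`, and `N = 5000` (estimation study) or `N = 1000` (model-selection
study). A generator of random regimes (`β` from a rescaled
Multinomial(100, 1/K) draw, `φ ~ U(0.5, 0.95)`, `p ~ U(0.1, 0.4)`) is
included for new experiments.

The study harnesses run simulate → fit per replicate (penalized refits are
warm-started from the unpenalized optimum), exclude and count non-converged
replicates (aborting beyond 20% failures), and summarize per parameter the
mean, RMSE, 95% CI coverage and mean CI width, or the per-model minimum-AIC
selection counts. All randomness flows from one seed through
`SeedSequence`-derived per-replicate streams, so studies are exactly
reproducible. The defaults — 30 replicates for estimation summaries, 60 for
selection counts (`scripts/acceptance.py`) — keep a full study on one CPU in
minutes while leaving Monte-Carlo noise small enough to compare against
100-replicate references: at 30 replicates the standard error of a coverage
percentage near 95% is ~4 points, and at 60 replicates a selection
proportion near 0.65 carries ~6 points; test tolerances are derived from
these binomial/normal errors.

### What the simulator does and does not emulate

It generates data exactly from the fitted model family: multinomial sampling
of latent histories with homogeneous per-occasion capture, permanent
emigration and closed periods. It does **not** emulate individual
heterogeneity, temporary emigration, within-period entry/exit (the closure
violations suspected in real amphibian data), tag loss, or misreads. Passing
tests therefore demonstrate correct inference *under the model*, not
robustness to these violations.

## Numerical accuracy of the approximation

The first-order saddlepoint pmf carries a smooth O(1/N) relative bias whose
constant grows with the length `L` of the observed vector. Exhaustive
enumeration on tiny designs shows ≈3% error for a single binomial count at
`N = 10`, ≈7% for three counts at `N = 20`, ≈13% for five counts at
`N = 20`, halving each time `N` doubles. Near the boundary of the feasible
cone (`Tx = y` almost uniquely solvable) the approximation can overshoot by
orders of magnitude — likelihood *ratios* remain far better behaved, which
is why estimation at realistic `N` is accurate even though the absolute pmf
at `N ≤ 20` is not. The test suite asserts both the bulk accuracy at small
`N` and the O(1/N) decay.

## Known limitations

* Designs are capped at `T ≤ 24` occasions by default (the full-enumeration
  `2^T` strategy; the cap is an argument, not a hard limit).
* Unmarked-but-released individuals are not modelled; all captured unmarked
  animals are assumed marked.
* Wald intervals degrade at boundary estimates by construction; the penalty
  is the supported remedy (no profile or bootstrap intervals).
* AIC uses the saddlepoint (optionally penalized) objective; its absolute
  value is not comparable across different history reductions, only across
  models fitted with the same reduction — matching how the model comparison
  table is built.
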