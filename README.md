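# batchmark

Maximum-likelihood inference for **extended batch-mark capture–recapture
studies** — studies in which animals are too small, too numerous or too
fragile to mark individually, so every animal caught in a primary period
receives the same batch mark (e.g. a VIE colour). The observed data are then
not individual capture histories but a set of counts: the number of animals
first marked on each secondary occasion, and the number of recaptures of each
marked cohort on each later occasion.

## The model

The unobserved process is a POPAN-style open-population model under the
robust design: `K` primary periods (population closed within a period, open
between periods), period `k` containing `T_k` secondary occasions. Each of
the `N` superpopulation members enters in period `k` with probability
`β_k` (`Σβ_k = 1`), survives from period `k` to `k+1` with probability `φ_k`
(emigration permanent), and while present is caught on occasion `(k, t)` with
probability `p_kt`. The vector `x` of counts of the `J = 2^T` latent capture
histories is then multinomial,

    x ~ Multinomial(N, π(θ)),   θ = (N, p, φ, β),

and the observed counts are a known 0/1 linear transform of it,

    y = T x,   T = (A′, B′)′,   m = A x  (first markings),  n = B x  (recaptures).

Because `T` is not invertible, the likelihood of `y` is an intractable sum
over all latent `x` consistent with the data. `batchmark` instead maximizes a
**saddlepoint approximation**: with `K_Y(s) = N log Σ_j π_j exp((T′s)_j)` the
cumulant generating function of `Y`,

    f̃(y; θ) = (2π)^{-L/2} |K″_Y(ŝ)|^{-1/2} exp{ K_Y(ŝ) − ŝ′y },

where `ŝ` solves `K′_Y(s) = y` (an `L`-dimensional convex problem solved by
damped Newton inside every likelihood evaluation). Standard errors come from
the observed information; an optional logit-normal penalty
`P = Σ logit(θ)² / (2σ_p²)` with `σ_p = 3` keeps probability estimates off
the 0/1 boundary when the data weakly identify them. Latent histories that
are impossible given the observed zeros are removed exactly; an optional
probability-based prefilter keeps only the most plausible fraction of
histories for large problems. Models are compared by AIC, with capture
structures `p(t) / p(k) / p(·)` and survival structures `φ(k) / φ(m) / φ(·)`
(`φ(m)` models a constant monthly survival `S` with `φ_k = S^{Δ_k}` for
unevenly spaced periods).

## Worked example

```python
import numpy as np
from batchmark import (BatchMarkModel, ParameterSet, StudyDesign,
                       simulate_dataset)

design = StudyDesign(K=3, Tks=(2, 2, 2))
truth = ParameterSet(N=500, p=np.full(6, 0.4), phi=[0.8, 0.7],
                     beta=[0.3, 0.4, 0.3])
data = simulate_dataset(truth, design, seed=1)
result = BatchMarkModel(data, model="p(t)phi(k)").fit()
print(result.summary())
```

prints (abridged):

```
Latent multinomial batch-mark model (saddlepoint ML)
  model: p(t)phi(k)   design: K=3, T=6
  likelihood: original
  latent histories retained: 64 (forced-zero dropped: 0)
  loglik: -40.6967   penalized: -41.6399   AIC: 103.39   k: 11

parameter  estimate      se      lcl      ucl
        N  507.5736 22.5172 465.3042 553.6829
    phi_1    0.7743  0.0867   0.5646   0.9008
    phi_2    0.9744  0.1686   0.0001   1.0000
   beta_1    0.3714  0.0485   0.2822   0.4704
   ...
     p_32    0.3109  0.0511   0.2204   0.4186

parameter  estimate    se    lcl    ucl
      N_1    188.52 24.95 145.45 244.35
      N_2    323.24 27.85 273.02 382.70
      N_3    456.74 68.33 340.67 612.36
```

`N` is the superpopulation size (everyone ever available for capture: truth
500, estimated 508 ± 23), `phi_k` the between-period survival, `beta_k` the
entry probabilities, `p_kt` the per-occasion capture probabilities, and
`N_k = N·ψ_k` the derived abundance present in period `k`. Wide survival
intervals (like `phi_2` above, whose estimate sits near 1) are the expected
signature of batch marking's weak survival information; refitting with
`penalize=True` pulls such estimates inside the interval and shrinks their
CIs.

A command-line interface wraps the same workflow:

```
batchmark simulate --design design.json --theta theta.json --seed 4 --out ds/
batchmark fit --design ds/design.json --marks ds/marks.csv \
    --recaptures ds/recaptures.csv --model "p(t)phi(k)" --out fit
batchmark select --design ... --models "p(t)phi(k),p(t)phi(.)" --out sel.tsv
batchmark study --config study.yaml --out study.tsv
```

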