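# qrer — quasi-rerandomization balancing weights

`qrer` implements **quasi-rerandomization (QReR)**, a reweighting method for
causal inference in observational two-arm studies that makes explicit *which*
randomized experiment the balanced data emulate: a **rerandomized** one.

Rerandomization (ReR) redraws a complete-randomization allocation `T~` with
fixed group sizes until the Mahalanobis distance between arm covariate means

```
D(X, T~) = (N1 N0 / N) · Δ(T~)ᵀ cov̂(X)⁻¹ Δ(T~),   Δ(T~) = X̄1 − X̄0,
```

falls below the `p_a` quantile of χ²_d.  In an observational study the real
allocation is fixed, but the covariates can still be rerandomized: QReR
draws per-arm flat Dirichlet weight vectors `W = (W1, W0)` and trains a
neural transformation `W~ = G(W | X, θ)` (two 512-unit ReLU layers, dropout
0.5, double softmax head) so that the *weighted* covariate mean differences
`Δ(W~) = Σᵢ W̃ᵢTᵢXᵢ − Σᵢ W̃ᵢ(1−Tᵢ)Xᵢ` match the distribution of `Δ(T~)`
from accepted allocations, by minimizing

```
L(θ) = L_MMD(θ) + λ₁ R₁(θ) + λ₂ R₂(θ)
```

— a kernel maximum mean discrepancy plus regularizers anchoring both
weighted arm means to the pooled mean (R₁) and discouraging extreme weights
(R₂).  The trained generator yields balancing weights for any weighted
estimator of the average treatment effect: the weighted mean difference
from a single vector (`QReR_S`), its ensemble over M = 1000 vectors
(`QReR_M`), and a weighted linear model with sandwich variance for
population-effect intervals.

Audience: biostatisticians and epidemiologists analyzing non-randomized
treatment comparisons who want design-stage covariate balance with an
explicit randomized-experiment target, plus a fully scripted synthetic
benchmark for method evaluation.

## Worked example

`python examples/fit_and_estimate.py` builds a 120-unit study whose treated
arm is shifted on two confounders (true effect 1.0), trains a small QReR
generator, and prints:

```
stopping metric: 1.000 (untrained) -> 0.148 (best, iteration 350)
raw mean difference : 3.155   (confounded; truth is 1.0)
QReR_S (one vector) : 1.058
QReR_M (M=1000)     : 1.210
robust 95% interval : [0.235, 2.186] (se 0.498)
```

The untrained generator's weighted Mahalanobis distances look nothing like
the rerandomized ones (KS statistic 1.0); training drops the metric to
0.148.  The raw difference overstates the effect by ~2.2 because the
treated arm has larger confounder values; the QReR estimates remove almost
all of that bias, and the robust interval covers the truth.  The other
examples cover the rerandomization engine (`examples/rerandomize_pool.py`)
and the simulation benchmark (`examples/simulation_benchmark.py`, which
also shows the rerandomization precision gain: linear-surface RMSE 0.54
under complete randomization vs 0.31 at acceptance probability 0.1).

A thin CLI mirrors the library for shell pipelines:
`qrer rerandomize | fit | estimate | simulate | balance-report`
(CSV in, CSV/JSON out; `qrer fit --config overrides.yaml` overrides any
training parameter).

## Synthetic benchmark

`qrer.simbench` regenerates the evaluation study: 8 covariates (4 Gaussian,
4 Bernoulli, every true standardized mean difference 0.2 or 0.5 by design),
three covariate scenarios, N1 = 250 treated vs N0 = r·250 controls
(r ∈ {1,2}, nested datasets), three response surfaces of increasing
nonlinearity with additive effect τ = 1, and bias/RMSE/Monte-Carlo-SE
aggregation over replicates plus per-covariate Kolmogorov–Smirnov balance
comparisons.  See `docs/methods.md` for the model, the training loop,
problem sizes, and design choices.

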