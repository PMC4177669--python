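# enzopt

**Optimal enzyme regulation under environmental and sensory uncertainty.**

A cell regulating a metabolic enzyme faces a decision problem: the nutrient
concentration *S* it must respond to fluctuates in time, its sensors return
only a noisy readout *m* of *S*, and expressing enzyme at level *E* brings
both a metabolic benefit and a synthesis cost. `enzopt` computes the
regulatory strategy — the mapping from readout(s) to enzyme level — that
maximizes the expected net payoff

```
P(E, S) = B(E, S) − C(E),    B = b·E·S  (or b·E·S/(K_M + S)),    C = c·E^α
```

given the statistics of the environment, the precision of the sensor, and
the convexity of the cost. It is aimed at systems and quantitative
biologists studying nutrient sensing, gene-regulatory strategy, and the
fitness value of cellular information processing.

## What the theory says (and the package computes)

- **Graded vs. thresholded response.** With benefit ∝ E^γ and cost ∝ E^α,
  the perfect-measurement optimum is a continuous (graded) function of *S*
  when cost is convex relative to benefit (α > γ), and an all-or-none
  switch between 0 and E_max at the break-even nutrient level
  S_t = (c/b)·E_max^(α−1) when α < γ.
- **Naive → Bayesian → constitutive.** With Gaussian readout noise
  (σ_m) and an environmental prior, the optimal response depends on the
  environment only through the posterior mean E[S | m]. For a Gaussian
  prior N(μ, σ_E²) this is the shrinkage estimate (m + βμ)/(1 + β) with
  **β = σ_m²/σ_E²** (inverse signal-to-noise ratio): β ≪ 1 gives naive
  response to the readout, β ≫ 1 gives constitutive expression at the
  level set by μ, and intermediate β gives a genuine Bayesian decision
  rule.
- **Bimodal environments classify.** For an equiprobable two-Gaussian
  environment (mode separation Δμ), the posterior mean takes a sigmoidal
  (tanh) form whose steepness is Δμ/(σ_E² + σ_m²); the distinguishability
  parameter **ξ = σ_m²/(Δμ·√(σ_E² + σ_m²))** separates classification
  (ξ ≪ 1), ambiguous inference, and constitutive response (ξ ≫ 1).
- **Memory pays at intermediate noise.** In a stationary mean-reverting
  AR(1) environment with persistence λ (correlation time τ = −1/ln λ), the
  optimal estimate given current and past readouts is exactly the Kalman
  filter; conditioning on the previous readout yields a fitness gain that
  peaks at intermediate β and vanishes in both noise extremes.

Every closed form is validated in the test suite against independent
brute-force oracles: adaptive quadrature for posterior expectations, dense
grid search for payoff maximization, the sequential Kalman recursion (and
statsmodels' state-space filter), and Monte-Carlo fitness estimation.

## Worked example

```python
import numpy as np
from enzopt import *

payoff = PayoffSpec(alpha=2.0)              # quadratic cost, linear benefit
prior = GaussianPrior(mu=1.0, sigma_E=1.0)
meas = MeasurementModel(sigma_m=1.0)        # beta = 1: ambiguous measurement

for m in (0.0, 1.0, 3.0):
    s_hat = posterior_mean_gaussian(m, prior, meas)
    e_star = optimal_enzyme_graded(payoff, max(s_hat, 0))
    print(f"m = {m:3.1f}  ->  E[S|m] = {s_hat:4.2f}  ->  E* = {e_star:5.3f}")

env = MarkovEnvSpec(mu=1.0, sigma_E=1.0, lam=0.9)   # persistent environment
strategies = build_reference_estimators(payoff, env, meas)
comp = compare_strategies(strategies, payoff, env, meas, n=1_000_000, seed=0)
print(comp.to_frame().to_string(index=False))
```

prints

```
m = 0.0  ->  E[S|m] = 0.50  ->  E* = 0.250
m = 1.0  ->  E[S|m] = 1.00  ->  E* = 0.500
m = 3.0  ->  E[S|m] = 2.00  ->  E* = 1.000
     strategy  mean_payoff  standard_error
        naive     0.297198        0.002195
 constitutive     0.246658        0.001912
        bayes     0.368177        0.002175
bayes_memory1     0.396944        0.002243
bayes_memory2     0.406544        0.002271
```

At β = 1 the Bayesian rule shrinks each readout halfway toward the prior
mean before responding (E* = E[S|m]/2 for quadratic cost), and in the
persistent environment it beats both the naive and the constitutive
strategy; each extra readout of memory buys a further, shrinking, fitness
increment.

Strategies are scikit-learn-style estimators (`fit`/`predict`,
`get_params`); `tabulate(grid)` exports the classical grid representation
(`StrategyTable`) that serializes to CSV with a JSON metadata sidecar.

## Command line

```bash
enzopt strategy   --config model.yaml --out strategy.csv --mode bayes
enzopt simulate   --config model.yaml --out trajectory.csv --n-steps 10000
enzopt compare    --config model.yaml --out comparison.csv --n 1000000
enzopt regime-map --config model.yaml --out regimes.csv --family markov
enzopt memory-value --config model.yaml --out memory.csv
```

with `model.yaml` like

```yaml
payoff: {benefit_mode: linear, b: 1.0, c: 1.0, alpha: 2.0}
prior: {kind: gaussian, mu: 1.0, sigma_E: 1.0}
measurement: {sigma_m: 1.0}
environment: {mu: 1.0, sigma_E: 1.0, lam: 0.9}
```

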