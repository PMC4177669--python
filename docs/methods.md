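# Methods

## Model

The decision problem is the regulation of a single metabolic enzyme.  At
each instant the cell holds enzyme at level E while the environment offers
nutrient at concentration S; the instantaneous payoff is

    P(E, S) = B(E, S) − C(E)

with benefit B either linear in both arguments (b·E·S, the unsaturated
Michaelis–Menten limit S ≪ K_M), hyperbolic in nutrient
(b·E·S/(K_M + S)), or — to probe the convexity theory — a power law
b·S·E^γ in enzyme; and cost the power law C(E) = c·E^α.  Fitness is the
*expectation* of P over the joint law of environment and readout: no
variance or higher-moment sensitivity is modeled, which is exactly what
makes posterior means sufficient statistics below.  The cell is assumed to
respond faster than the environment changes (no response lag), to set E
deterministically given its readout(s), and to pay nothing for the
regulatory machinery itself.

### Perfect measurement

Maximizing P in E at known S splits on the exponent pair:

- **α > γ** (cost convex relative to benefit): unique interior optimum
  E*(S) = (γ·u(S)/(α·c))^(1/(α−γ)), with u(S) the benefit's coefficient of
  E^γ (u = b·S for the linear mode, u = b·S/(K_M+S) for Michaelis–Menten).
  The optimal response is graded: continuous and nondecreasing in S.
- **α < γ**: the payoff has no interior maximum on E ≥ 0, so the optimum
  sits on the boundary {0, E_max} — thresholding at the break-even
  nutrient level where P(E_max, S_t) = 0 (S_t = (c/b)·E_max^(α−1) for the
  linear benefit).  A finite E_max is required and enforced.
- **α = γ**: payoff is linear in E^α; handled as thresholding at the point
  where the linear coefficient changes sign.  At the exact threshold the
  two boundary payoffs tie at zero and the implementation returns 0 (no
  production), the parsimonious tie-break.

An interior optimum exceeding a finite E_max clamps to E_max.

### Noisy measurement

Readouts are unbiased and Gaussian: m = S + ε, ε ~ N(0, σ_m²).  Because the
(retained) benefit is linear in S, the conditional expected payoff given m
is b·E·E[S|m] − c·E^α, so the optimal response is the perfect-measurement
optimum evaluated at the posterior mean.  Closed forms implemented:

- Flat prior: E[S|m] = m (the naive response is optimal).
- Gaussian prior N(μ, σ_E²): E[S|m] = (m + βμ)/(1 + β) with
  β = σ_m²/σ_E², posterior variance σ_m²/(1+β).
- Gaussian mixture: responsibility-weighted per-mode shrinkage,
  w_i(m) ∝ p_i·N(m; μ_i, σ_i² + σ_m²), each mode contributing
  (m + β_i μ_i)/(1 + β_i) with β_i = σ_m²/σ_i².  Computed with
  log-sum-exp, so tail readouts are stable.  For the equiprobable
  equal-σ bimodal prior this reduces to an explicit tanh form whose
  steepness is Δμ/(σ_E² + σ_m²); both routes are implemented and tested
  for algebraic identity.

β is defined as σ_m²/σ_E² — the *inverse* signal-to-noise ratio — so that
β ≪ 1 is the naive regime and β ≫ 1 the constitutive regime.  The bimodal
distinguishability parameter is ξ = σ_m²/(Δμ·√(σ_E² + σ_m²)), reading
"measurement uncertainty" as the variance and "typical distance of a
measurement from the mean" as the total standard deviation; since this
convention is not forced, `xi_ratio` is a plain function that can be
swapped out, and `sigma_m_for_xi` inverts it when building sweeps.  The
regime classifier's cut points (0.1 and 10) are presentation defaults on a
gradual transition, configurable per call.

Gaussian priors put mass on negative concentrations.  Posterior means are
computed on the full real line (matching the closed forms); the *effective*
nutrient level is clamped at zero before entering the static optimum, which
is exactly optimal because for a nonpositive posterior mean the expected
payoff is maximized at E = 0.  Monte-Carlo fitness evaluation likewise uses
the signed linear payoff, so Bayes strategies remain exactly optimal under
the generating model.  A truncated-prior variant is available through the
quadrature oracle only.

Michaelis–Menten benefit under noise requires E[S/(K_M+S)|m], which has no
closed form here; the strategy constructors reject that combination and
point to `posterior_functional_quadrature`.

### Dynamic environment and memory

The environment is a stationary mean-reverting AR(1) chain:
S_t | S_{t−1} ~ N(λ·S_{t−1} + (1−λ)·μ, σ_d²) with σ_d² = (1−λ²)·σ_E²
derived from (μ, σ_E, λ) so that the marginal N(μ, σ_E²) is constant by
construction and the lag-k autocorrelation is λ^k (correlation time
τ = −1/ln λ; τ = 0 at λ = 0 by convention; λ = 1 is excluded — a plain
random walk has no stationary law).  One discrete step equals one
measurement interval.

Everything is jointly Gaussian, so E[S_t | m_t, …, m_{t−k}] is linear in
the readouts with weights from a (k+1)-dimensional solve of the normal
equations (Cov(S_t, m_{t−j}) = λ^j σ_E²; Cov(m_i, m_j) = λ^|i−j| σ_E² +
δ_ij σ_m²).  This single implementation provides the memory-1 and memory-2
posterior means and arbitrary k; it coincides with the sequential Kalman
recursion, which is implemented independently in `enzopt.oracles` and
asserted equal to 1e-8 over random parameter draws (plus a cross-check
against statsmodels' state-space filter and an OLS regression on 10⁷
simulated triples).  The optimal dynamic strategy composes the static
optimum with the clamped memory posterior mean on a 2-D readout grid.

## Strategy estimators and tables

Strategies are scikit-learn-style estimators (`NaiveResponse`,
`ConstitutiveResponse`, `BayesResponse`, `MemoryBayesResponse`): parameters
are model specifications, `fit` validates them and precomputes fitted
quantities (shrinkage weights, constitutive level), `predict` maps readout
columns to enzyme levels.  The classical representation — a strategy
tabulated on a readout grid — is exported by `tabulate` as a
`StrategyTable` (1-D) or `StrategyTable2D` (current × previous readout).
Consumers interpolate linearly between nodes; readouts outside the grid
clamp to the edge levels.  Tables round-trip to CSV (long format for 2-D)
with a JSON metadata sidecar.  Strategies with memory ≥ 2 have no table
form and are used as estimators directly.

## Synthetic data

The simulator draws i.i.d. samples from the static priors, stationary AR(1)
trajectories (S₀ from the marginal, then the conditional recursion run as a
linear filter), and Gaussian readout corruption.  Environment and
measurement noise come from independent substreams spawned from one seed,
so σ_m can be varied while holding the environmental path fixed — this is
what makes the paired value-of-memory comparisons sharp.  Everything is
bit-exactly reproducible from (spec, seed).

The generator emulates exactly the distributional assumptions of the
theory: Gaussian or Gaussian-mixture marginals, linear-Gaussian dynamics,
unbiased Gaussian sensors.  It does not emulate features of real nutrient
data — non-negativity of concentrations, heavy tails, non-Markov structure,
intracellular expression noise, or sensor bias — so passing tests certify
the mathematics of the decision rules under their stated model, not their
robustness on real signals.

## Numerical choices

- Quadrature oracle: posterior expectations by adaptive quadrature over a
  window of ±8 combined standard deviations around every relevant center,
  segmented at each sharp feature (readout ± 10σ_m, mode means ± 10σ_i) so
  narrow likelihood spikes inside a wide window are never missed;
  tolerances 1e-13 absolute / 1e-12 relative, results invariant to 1e-8
  under doubling of the window.  A vanishing normalizer (readout far
  outside the window) raises rather than returning garbage.
- Grid-search oracle: payoff argmax on dense enzyme grids (step 1e-4 in
  the tests); ties resolve to the smallest enzyme level.
- Monte-Carlo fitness: common random numbers across compared strategies;
  standard errors by batch means (100 batches) on trajectories, where
  payoffs are serially correlated, and by the i.i.d. formula otherwise;
  n < 100 is refused.
- Autocorrelation checks use Bartlett's closed-form standard error for
  geometric correlation; stationary mean and variance checks use the
  matching AR(1)-adjusted standard errors.

## Problem sizes

Unit and property tests run at small n (10³–10⁵).  The validation pipeline
uses 200 random draws per prior family for quadrature agreement, 100 draws
for Kalman agreement, 10⁵-step trajectories for simulator recovery, 10⁷
triples for the regression cross-check, and 10⁶ Monte-Carlo samples per
cell for the fitness ordering over the 5×4 (β, λ) sweep and the
value-of-memory sweep β ∈ {10⁻², 10⁻¹, 1, 10, 10²} at λ = 0.9.  At these
sizes the full suite completes in well under a minute on one CPU.  The
"vanishes at the extremes" claim for the value of memory is checked
relative to its peak (edge values below 10% of the maximum) because the
quantity is analytically positive everywhere — it is a paired expected
squared-difference of two posterior means — and only tends to zero in the
limits β → 0 and β → ∞.

## Default study conditions

Dimensionless units with b = c = K_M = 1: results depend only on the
ratios β, ξ, λ and the exponents (α, γ).  The canonical convex case is
quadratic cost (α = 2) with linear benefit; the canonical environment is
μ = 1, σ_E = 1 (a nutrient scale of order its own variability, so naive,
Bayesian and constitutive responses genuinely differ), persistence λ = 0.9
for dynamic analyses (correlation time ≈ 9.5 steps, long enough for memory
to matter), and bimodal mode width σ = 0.1 with separation Δμ = 2 (tight,
well-separated modes, the classification-friendly regime).

## Known limitations

- Closed-form noisy strategies exist only for benefit linear in S; the
  Michaelis–Menten case under noise is oracle-only.
- Memories longer than two past readouts are supported through the generic
  Gaussian-conditioning/Kalman route, not as separate closed forms.
- No continuous-time (Ornstein–Uhlenbeck) treatment, no response lag, no
  stochastic (bet-hedging) strategies, and no fitness sensitivity to payoff
  variance; these are outside the model class by design.
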