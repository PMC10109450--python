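# Methods

## Model and assumptions

The package treats growth as proportional betting in a stationary
stochastic environment. A population of *N* agents shares the
*statistics* of one environment — every draw any agent ever sees comes
from the same joint law P(E, S) — but never its realizations: signals
and events are sampled independently per agent and per bet. There is no
interaction, redistribution, debt, or birth–death; resources evolve
purely multiplicatively, so they remain strictly positive.

The standard environment is the degenerate multinomial channel: events
and signals share an alphabet of size *l*, the conditional P(e|s) puts
probability *p* on the diagonal and spreads the remainder uniformly,
and marginals are uniform (hence P(e|s) = P(s|e)). Odds default to fair
(w_e = l), which is what makes mutual information the growth ceiling;
arbitrary positive odds are accepted by the general calculator
`growth_rate_general` but not used in the replication presets.

All information and growth quantities are computed and stored in
natural logarithms (nats); `nats_to_bits` divides by log 2 for display.
The 0·log 0 ≡ 0 convention applies throughout. Impossible allocations
are signalled with ±inf sentinel values rather than exceptions so that
parameter sweeps run to completion.

## Time scaling

One unit of simulated time comprises ω independent bets, and the
unit-time resource update is the *geometric* mean of the ω gross
multipliers. Geometric averaging is the choice that preserves both
defining contracts simultaneously: the expected log increment per unit
time equals the per-bet Kelly rate γ, and the unit-time volatility is
σ/√ω. (Arithmetic averaging of gross returns would bias the drift
upward by a Jensen term and break the second relation.) In the static
case the log resources then perform a random walk with drift γ and step
standard deviation σ/√ω — discrete-time geometric Brownian motion —
which the tests verify with a Kolmogorov–Smirnov check and the
⟨r(t)⟩ = exp(γt) moment identity.

Simulation time is abstract "unit time"; rates of a few 0.01 nats per
unit time correspond to the familiar few-percent-per-year regime of
empirical wealth dynamics, but no calendar mapping is enforced.

## Bayesian updating

Each learning agent keeps a Dirichlet–categorical posterior over the
channel: uniform event pseudo-counts (α_e = 1), likelihood parameters
β[s,e] frozen at the degenerate pattern f(x₀, l), and raw integer
(signal, event) counts m[s,e]. The allocation after observing counts is

X(e|s) ∝ (m[s,e]/(ωk) + β[s,e]) / (M_s/(ωk) + 1) · (n_e + α_e),

normalized over events at evaluation time (the signal-total denominator
is event-independent and cancels, but is kept in the scalar API for
transparency). Counts are scaled by 1/(ωk) at *read* time so they stay
integral; after t unit times each signal carries evidence weight
t/(kl) against the prior's weight of 1, which is exactly what produces
the closed-form mean trajectory x(t) = (p·t/kl + x₀)/(1 + t/kl).

Two consequences worth knowing:

- The allocation at any bet uses only the counts of *previous* bets;
  the observation is folded in after the payout resolves. An agent
  never conditions on the outcome it is betting on.
- The event-marginal factor (n_e + α_e) is not damped by k. Under the
  uniform event marginal it is balanced in expectation and cancels in
  the normalization, so the documented k → ∞ (frozen prior) and k → 0
  (maximum likelihood) limits hold for marginally balanced evidence —
  the regime environment-driven evidence occupies on average — and the
  closed-form trajectory is unaffected. For deliberately unbalanced
  count patterns the factor tilts the posterior toward oversampled
  events, which is faithful Bayesian behavior for the event prior.

Inference time defaults to k = 1 time/update; ω defaults to 100 bets
per unit time. Both are package choices: they place learning on the
same time scale as the growth dynamics (λ = t/kl reaches 1 within a few
unit times) and make the unit-time increments near-Gaussian.

## Population engines

`step_agent` is the per-bet reference implementation. The simulator
uses two equivalent, vectorized engines:

- **Static beliefs.** With a degenerate policy and fair odds the
  per-bet log return takes exactly two values (log xl with probability
  p, log[(1−x)l/(l−1)] otherwise), so the unit-time increment is an
  exact function of a Binomial(ω, p) win count. This is an identity,
  not an approximation; a test pins the engine's increments to the
  two-point lattice and its moments to the closed forms.
- **Learning beliefs.** All agents advance in lockstep, one bet at a
  time, with array-valued draws indexed by agent; the count tensors and
  posterior evaluation replicate the scalar update exactly.

Randomness comes from one master `SeedSequence` split into
purpose-specific child streams (initialization vs. betting). Agent *i*
always occupies column *i* of every array draw, so results are
bit-reproducible from the seed and stable in agent ordering. This
replaces literal one-generator-per-agent splitting with an equivalent
scheme that vectorizes.

Heterogeneous populations draw growth rates from Normal(γ̄, σ_γ),
reject and redraw outside (ε, I(E;S) − ε) with ε = 10⁻⁶, and invert
γ(x) on a single chosen branch so all agents are conservative (or all
aggressive). The replication preset uses γ̄ = 0.04, σ_γ = 0.641·γ̄,
conservative, for which truncation is a negligible tail effect
(verified by re-evaluating γ on the sampled beliefs).

## Numerical choices

- Branch inversion solves γ(x) = γ* by Brent's method with brackets
  nudged 10⁻⁹ inside the open interval; the aggressive bracket's upper
  end is the nontrivial root of γ(x) = 0, itself found by Brent. The
  round-trip is accurate to ≲10⁻¹² in γ.
- Targets within 10⁻¹⁵ of the mutual information return x = p directly
  to avoid bracketing a vanishing interval around the maximum.
- Gini uses the sorted-rank form of the pairwise mean-absolute-
  difference definition with the population 1/(2N²⟨r⟩) normalization
  (endpoints 0 and (N−1)/N), O(N log N); variances and covariances use
  the population (1/N) convention.
- The lognormal Gini approximation is the standard closed form
  erf(σ_log r / 2).
- CSV output uses 17 significant digits and round-trip float parsing,
  so written artifacts reproduce bit-identically.

## Scales used by the verification suite

The test suite and `scripts/acceptance.py` run the experiments at their
stated scales: N = 388 homogeneous agents at γ = 0.03 over T = 100 unit
times of ω = 100 bets (growth-rate recovery and the ≤15% convergence
bound at t = 80, each over a fixed 10-seed bank requiring ≥9 passes);
N = 10³, T = 100 for the homogeneous/heterogeneous/learning inequality
triple; 10³ replicate belief streams for mean-trajectory recovery; 10⁶
sampled bets per grid point for the per-bet moment checks.

One check needs care: comparing the *empirical* population belief
variance of a finite-ω simulation against the deterministic-trajectory
decay law Var[x(t)] = σ²ₓ₀/(1 + t/kl)². The law describes the spread of
the mean paths; a simulation at observation rate ω adds sampling noise
of relative order p(1−p)·t/(ω·σ²ₓ₀(kl)²), which grows linearly in t
while the Monte-Carlo resolution of a variance estimate stays at
≈4·√(2/N). The check therefore uses a high observation rate (ω = 10⁴)
and N = 10⁴ agents with checkpoints inside the first decade of the
decay (t ∈ {1, 2, 3, 5, 10} at k = 1, l = 2), where the correction sits
below resolution; the t⁻² asymptote itself is verified on the closed
form over t ∈ [10³kl, 10⁴kl].

## What the simulator does and does not emulate

The generator reproduces the study conditions: a stationary,
degenerate-multinomial environment with fair odds, iid private signals,
Gaussian growth-rate heterogeneity mapped to one volatility branch, and
experiential (bet-by-bet) Bayesian learning with a common k. Passing
tests therefore demonstrate internal consistency of theory and
simulation under these conditions. They do not speak to non-stationary
environments, shared shocks (common realizations across agents),
misspecified likelihood families, signal-access inequality, learning
rates coupled to wealth, or redistribution — all deliberately out of
scope. The growth-rate variance decomposition Var[γ] = Var[I] + Var[D]
− 2·Cov[I, D] is implemented and tested as an identity, but no
misspecified-model preset (Var[I] ≠ 0) is provided.

## Known limitations

- Resources are tracked in level form for outputs; runs combining very
  long horizons with aggressive branches can overflow the exponential
  (log-resources are the internal representation, and Gini/c_v are
  computed scale-invariantly, but `mean_r` can saturate).
- The belief-variance comparison above is regime-limited by finite ω,
  as described; at late times the observation-noise floor (∝ 1/ωt)
  dominates the t⁻² signal for any fixed ω.
- `step_agent`'s per-bet scalar path is O(ω) Python per agent and is
  meant as a reference and for small runs; large experiments should go
  through `simulate_population`.
- The rejection sampler for heterogeneous rates slightly truncates the
  Gaussian; at the preset parameters the bias is far below Monte-Carlo
  error, but extreme (γ̄ near 0 or near I(E;S), large σ_γ) settings
  shift the realized mean visibly.
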