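# infogrowth

Information-driven growth and inequality dynamics in shared noisy
environments.

`infogrowth` is for researchers studying stochastic multiplicative
(wealth- or fitness-like) dynamics who want growth rates derived from
*behavior* rather than postulated: agents repeatedly bet resources on
uncertain environmental events using private signals, and their long-run
growth rate is an information-theoretic quantity. The package provides
the closed-form theory, a sequential Bayesian learning model, a seeded
agent-based Monte-Carlo simulator, and inequality metrics (Gini,
coefficient of variation, growth-rate variance decomposition).

## The model

At each betting step an agent observes a private signal *s* and splits
its resources over all possible events with fractions *B*(*e*|*s*); the
realized event *e* pays *w_e* per unit wagered. Over many bets the
resources grow exponentially at the Kelly rate

γ = Σ_{e,s} P(s, e) log[ B(e|s) · w_e ]   (nats per bet),

which under fair odds (w_e = 1/P(e)) and an optimal allocation
B = X(E|S) given the agent's belief X decomposes as

γ = I(E; S) − E_s[ D_KL( P(E|s) ‖ X(E|s) ) ].

Mutual information is the ceiling on growth; the expected
Kullback–Leibler divergence between the true conditional and the
agent's belief is the price of ignorance.

The workhorse environment is the degenerate multinomial channel on an
alphabet of size *l*: P(e|s) = p if e = s, (1−p)/(l−1) otherwise, with
uniform marginals. Parameterizing the agent's belief by its diagonal
*x* gives closed forms:

- I(E;S) = log l + p log p + (1−p) log[(1−p)/(l−1)]
- γ(x) = log l + p log x + (1−p) log[(1−x)/(l−1)] (maximal at x = p)
- σ(x) = √(p(1−p)) · |log[x(l−1)/(1−x)]| (per-bet volatility)

With ω bets per unit time and geometric averaging, static-belief agents
perform geometric Brownian motion with drift γ and volatility σ/√ω; any
feasible rate maps to exactly two beliefs, a *conservative* (x < p, low
volatility) and an *aggressive* (x > p, high volatility) one.

Learning agents update a Dirichlet–categorical posterior after every
bet. Their effective diagonal belief relaxes hyperbolically,
x(t) = (p·t/kl + x₀)/(1 + t/kl), where the inference time *k* weighs
prior against evidence, and the population belief variance decays as
Var[x(t)] = σ²ₓ₀/(1 + t/kl)² — asymptotically t⁻². Learning therefore
raises mean growth *and* suppresses the growth-rate heterogeneity that
drives long-run wealth inequality.

## Worked example

```python
import numpy as np
from infogrowth import (EnvironmentSpec, PopulationConfig, kelly_decomposition,
                        invert_growth_rate, simulate_population, to_joint,
                        time_averaged_growth)
from infogrowth.learning import degenerate_pattern

env = EnvironmentSpec(l=2, p=0.7)
joint = to_joint(env)

# an agent who underestimates the channel (x = 0.6 instead of 0.7)
summary = kelly_decomposition(joint, degenerate_pattern(2, 0.6))
print(f"I(E;S)    = {summary.mutual_info:.4f} nats")
print(f"E_s[D_KL] = {summary.expected_kl:.4f} nats")
print(f"gamma     = {summary.gamma:.4f} nats/bet")
print(f"sigma     = {summary.sigma:.4f} nats/bet")

# the conservative belief that yields a 3%-per-unit-time growth rate
x = invert_growth_rate(2, 0.7, 0.03, "conservative")
print(f"x(gamma=0.03, conservative) = {x:.4f}")

# 388 homogeneous static agents, 100 unit times of 100 bets each
cfg = PopulationConfig(env=env, N=388, T=100, omega=100, r0=1.0,
                       mode="homogeneous", gamma_mean=0.03, seed=1)
traj = simulate_population(cfg)
conv = time_averaged_growth(traj, gamma_ref=0.03, t=100)
print(f"<G>(t=100)  = {conv.mean_G:.5f} nats/unit time")
print(f"<r>(t=100)  = {traj.aggregates['mean_r'].iloc[-1]:.2f}   "
      f"(exp(0.03*100) = {np.exp(3):.2f})")
print(f"Gini(t=100) = {traj.aggregates['gini'].iloc[-1]:.3f}")
```

Output:

```
I(E;S)    = 0.0823 nats
E_s[D_KL] = 0.0216 nats
gamma     = 0.0607 nats/bet
sigma     = 0.1858 nats/bet
x(gamma=0.03, conservative) = 0.5418
<G>(t=100)  = 0.03003 nats/unit time
<r>(t=100)  = 20.20   (exp(0.03*100) = 20.09)
Gini(t=100) = 0.042
```

Reading: the p = 0.7 binary channel supports at most 0.0823 nats of
growth per bet; believing x = 0.6 forfeits 0.0216 of it. A population
of 388 agents tuned to γ = 0.03 indeed averages a time-averaged growth
rate of 0.03003 nats per unit time, its mean wealth tracks exp(γt), and
homogeneous growth keeps inequality low (Gini ≈ 0.04).

## Command line

```bash
infogrowth analytics --l 2 --p 0.7 --x 0.6          # closed forms as JSON
infogrowth simulate --config run.yaml --out results  # seeded simulation
infogrowth preset fig2b --seed 3 --out out/fig2b     # canned experiments
```

`simulate` writes `aggregates.csv` (per-unit-time mean resources, Gini,
c_v, belief statistics, mean time-averaged growth), `inequality.csv`,
`resolved_config.json` (the exact reproducible configuration), and
`run.log`. Presets: `fig2b` (homogeneous γ = 0.03 population),
`fig2d` (same, longer horizon, convergence diagnostics), `fig4`
(homogeneous / heterogeneous / heterogeneous+learning triple with
γ̄ = 0.04, σ_γ = 0.641·γ̄).

## Documentation

`docs/methods.md` describes the model assumptions, parameter choices,
numerical decisions, what the simulator does and does not emulate, and
known limitations.
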