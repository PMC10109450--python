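"""Monte-Carlo population dynamics of betting, compounding, and learning.

``N`` agents repeatedly bet their resources on events of a shared
degenerate multinomial environment, each observing a private signal.
Time is organized as ``omega`` independent bets per unit time; the
resource update over one unit time is the geometric mean of the per-bet
gross multipliers,

    r(t + 1) = r(t) * ( prod_{j=1}^{omega} B_j(e_j) * w_{e_j} )^(1/omega),

so the mean log increment per unit time equals the per-bet Kelly rate
``gamma`` while the volatility is averaged down to ``sigma/sqrt(omega)``.
With static beliefs this is geometric Brownian motion in discrete time;
with learning on, each agent updates a Dirichlet-categorical posterior
after every bet and allocates with it.

Agents share the environment's *statistics*, never its realizations:
every draw is independent across agents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .environment import EnvironmentSpec, sample_step
from .infotheory import invert_growth_rate, mutual_information_multinomial
from .learning import (
    BeliefState,
    degenerate_pattern,
    init_belief,
    posterior_conditional,
    update_belief,
)

__all__ = [
    "AgentState",
    "PopulationConfig",
    "TrajectoryRecord",
    "GrowthConvergence",
    "sample_heterogeneous_x",
    "step_agent",
    "simulate_population",
    "belief_ensemble_x",
    "time_averaged_growth",
]

_REJECT_EPS = 1e-6


@dataclass
class AgentState:
    """One agent: resources plus either a static belief or a posterior."""

    resources: float
    belief: BeliefState | None = None
    learning: bool = False
    x_static: float | None = None

    def __post_init__(self) -> None:
        if self.resources <= 0:
            raise ValueError("resources must be strictly positive")
        if self.learning and self.belief is None:
            raise ValueError("a learning agent needs a BeliefState")
        if not self.learning and self.x_static is None:
            raise ValueError("a non-learning agent needs x_static")
        if self.x_static is not None and not (0.0 < self.x_static < 1.0):
            raise ValueError("x_static must lie in (0, 1)")


@dataclass(frozen=True)
class PopulationConfig:
    """Full parameterization of one population experiment.

    ``mode`` selects homogeneous initial beliefs (everyone at the
    ``gamma_mean`` growth rate) or heterogeneous ones (rates drawn from
    a Gaussian with mean ``gamma_mean`` and SD ``gamma_sd``, mapped to
    diagonal beliefs on one volatility ``branch``).  With ``learning``
    on, the sampled belief seeds each agent's prior and Bayesian
    updating is performed after every bet with inference time ``k``.
    """

    env: EnvironmentSpec
    N: int = 388
    T: int = 100
    omega: int = 100
    r0: float = 1.0
    mode: str = "homogeneous"
    gamma_mean: float = 0.03
    gamma_sd: float = 0.0
    branch: str = "conservative"
    learning: bool = False
    k: float = 1.0
    seed: int = 0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.N < 1 or self.T < 1 or self.omega < 1:
            raise ValueError("N, T, and omega must all be >= 1")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.branch not in ("conservative", "aggressive"):
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.gamma_sd < 0:
            raise ValueError("gamma_sd must be nonnegative")
        mi = mutual_information_multinomial(self.env.l, self.env.p)
        if not (0.0 < self.gamma_mean < mi):
            raise ValueError(
                f"gamma_mean must lie in (0, I(E;S)) = (0, {mi:.6g}), got {self.gamma_mean}"
            )
        if self.k <= 0:
            raise ValueError("inference time k must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class TrajectoryRecord:
    """Time-resolved output of one population run.

    ``aggregates`` holds one row per unit time (columns ``time, mean_r,
    var_r, gini, cv, mean_x, var_x, mean_G``); ``resources`` and
    ``x_values`` are snapshot matrices (snapshot time x agent) taken
    every ``record_every`` unit times, always including t = 0 and t = T.
    """

    times: np.ndarray
    snapshot_times: np.ndarray
    resources: np.ndarray
    x_values: np.ndarray
    aggregates: pd.DataFrame
    x_initial: np.ndarray
    config: PopulationConfig

    def aggregates_to_csv(self, path) -> None:
        self.aggregates.to_csv(path, index=False, float_format="%.17g")

    def agents_to_jsonl(self, path) -> None:
        """One JSON record per (snapshot time, agent); for small runs."""
        with open(path, "w") as fh:
            for ti, t in enumerate(self.snapshot_times):
                for i in range(self.resources.shape[1]):
                    fh.write(
                        json.dumps(
                            {
                                "time": int(t),
                                "agent": i,
                                "resources": float(self.resources[ti, i]),
                                "x": float(self.x_values[ti, i]),
                            }
                        )
                        + "\n"
                    )

    def snapshot_index(self, t: int) -> int:
        idx = np.flatnonzero(self.snapshot_times == t)
        if idx.size == 0:
            raise KeyError(f"no snapshot recorded at t={t}")
        return int(idx[0])


@dataclass(frozen=True)
class GrowthConvergence:
    """Time-averaged growth rates and their normalized gap to a target.

    ``G[i] = (1/t) ln(r_i(t)/r_i(0))``; ``delta = (gamma - G)/gamma``
    per agent, ``delta_mean`` the same gap for the population mean
    ``<G>``.
    """

    t: float
    G: np.ndarray
    mean_G: float
    delta: np.ndarray
    delta_mean: float


def sample_heterogeneous_x(
    N: int,
    gamma_mean: float,
    gamma_sd: float,
    env: EnvironmentSpec,
    branch: str = "conservative",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw N diagonal beliefs from a Gaussian law of growth rates.

    Rates are drawn from Normal(gamma_mean, gamma_sd); draws outside the
    feasible band ``(eps, I(E;S) - eps)`` are rejected and redrawn, then
    each rate is mapped to its unique diagonal belief on the requested
    volatility branch.
    """
    if rng is None:
        rng = np.random.default_rng()
    mi = mutual_information_multinomial(env.l, env.p)
    if not (0.0 < gamma_mean < mi):
        raise ValueError(f"gamma_mean must lie in (0, {mi:.6g}), got {gamma_mean}")
    gammas = rng.normal(gamma_mean, gamma_sd, size=N)
    bad = (gammas <= _REJECT_EPS) | (gammas >= mi - _REJECT_EPS)
    while np.any(bad):
        gammas[bad] = rng.normal(gamma_mean, gamma_sd, size=int(bad.sum()))
        bad = (gammas <= _REJECT_EPS) | (gammas >= mi - _REJECT_EPS)
    return np.array([invert_growth_rate(env.l, env.p, g, branch) for g in gammas])


def step_agent(
    agent: AgentState,
    env: EnvironmentSpec,
    omega: int,
    rng: np.random.Generator,
) -> AgentState:
    """Advance one agent by one unit time (omega sequential bets).

    Reference per-bet implementation: each bet draws (event, signal),
    allocates with the current belief (posterior if learning, static
    ``f(x, l)`` row otherwise), multiplies resources by the payout, and
    only then folds the observation into the belief.  The omega gross
    multipliers are combined by their geometric mean.
    """
    belief = agent.belief
    log_sum = 0.0
    for _ in range(int(omega)):
        e, s = sample_step(env, rng)
        if agent.learning:
            alloc = posterior_conditional(belief, s)
        else:
            alloc = degenerate_pattern(env.l, agent.x_static)[s - 1]
        log_sum += np.log(alloc[e - 1] * env.odds[e - 1])
        if agent.learning:
            belief = update_belief(belief, s, e)
    return AgentState(
        resources=agent.resources * float(np.exp(log_sum / omega)),
        belief=belief,
        learning=agent.learning,
        x_static=agent.x_static,
    )


def _initial_x(cfg: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.mode == "homogeneous":
        x = invert_growth_rate(cfg.env.l, cfg.env.p, cfg.gamma_mean, cfg.branch)
        return np.full(cfg.N, x)
    return sample_heterogeneous_x(cfg.N, cfg.gamma_mean, cfg.gamma_sd, cfg.env, cfg.branch, rng)


def _static_log_trajectories(
    cfg: PopulationConfig, x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(T+1, N) log-resource paths for fixed beliefs, exactly distributed
    as the per-bet process: each bet's log return is two-valued (win with
    probability p), so the unit-time increment is a scaled binomial."""
    env, T, N, omega = cfg.env, cfg.T, cfg.N, cfg.omega
    log_win = np.log(x * env.l)
    log_loss = np.log((1.0 - x) * env.l / (env.l - 1))
    wins = rng.binomial(omega, env.p, size=(T, N))
    dlog = (wins * log_win[None, :] + (omega - wins) * log_loss[None, :]) / omega
    out = np.empty((T + 1, N))
    out[0] = np.log(cfg.r0)
    np.cumsum(dlog, axis=0, out=out[1:])
    out[1:] += np.log(cfg.r0)
    return out


class _LearningEngine:
    """Vectorized per-bet Bayesian updating across all agents at once.

    Keeps the (signal, event) count tensors of the whole population and
    replays, in lockstep, exactly the bet-allocate-update cycle of
    ``step_agent``.  The posterior's signal-total denominator is
    constant across events and cancels in the normalization, so it is
    omitted from the allocation weights.  Uniform event pseudo-counts
    (alpha_e = 1) are assumed.
    """

    def __init__(
        self,
        env: EnvironmentSpec,
        x0: np.ndarray,
        omega: int,
        k: float,
        rng: np.random.Generator,
    ):
        self.env = env
        self.omega = int(omega)
        self.rng = rng
        l, N = env.l, len(x0)
        self.m = np.zeros((N, l, l))
        self.n = np.zeros((N, l))
        self.x0 = np.asarray(x0, dtype=float)
        self.off = (1.0 - self.x0) / (l - 1)
        self.wk = omega * k
        self._rows = np.arange(N)

    def unit_time(self) -> np.ndarray:
        """Run omega bets for every agent; returns per-agent log increments."""
        env, omega = self.env, self.omega
        l, p = env.l, env.p
        N = len(self.x0)
        rows = self._rows
        log_sum = np.zeros(N)
        for _ in range(omega):
            e = self.rng.integers(0, l, size=N)
            hit = self.rng.random(N) < p
            offset = self.rng.integers(1, l, size=N)
            s = np.where(hit, e, (e + offset) % l)
            # posterior weights over events for each agent's drawn signal
            m_rows = self.m[rows, s]                      # (N, l)
            beta_rows = np.broadcast_to(self.off[:, None], (N, l)).copy()
            beta_rows[rows, s] = self.x0
            num = (m_rows / self.wk + beta_rows) * (self.n + 1.0)
            alloc_e = num[rows, e] / num.sum(axis=1)
            log_sum += np.log(alloc_e * env.odds[e])
            self.m[rows, s, e] += 1.0
            self.n[rows, e] += 1.0
        return log_sum / omega

    def effective_x(self) -> np.ndarray:
        """Current diagonal-average belief of every agent."""
        l = self.env.l
        beta = np.empty_like(self.m)
        beta[:] = self.off[:, None, None]
        idx = np.arange(l)
        beta[:, idx, idx] = self.x0[:, None]
        num = (self.m / self.wk + beta) * (self.n + 1.0)[:, None, :]
        post = num / num.sum(axis=2, keepdims=True)
        return post[:, idx, idx].mean(axis=1)


def belief_ensemble_x(
    env: EnvironmentSpec,
    x0: np.ndarray | float,
    T: int,
    omega: int = 100,
    k: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve an ensemble of belief streams without resource tracking.

    Each stream observes its own iid (event, signal) draws from ``env``
    at ``omega`` observations per unit time and performs the standard
    Bayesian update.  ``x0`` may be a scalar (replicate streams from one
    prior) or a length-N array.  Returns ``(times, X)`` with ``X`` of
    shape (T+1, N) holding every stream's effective diagonal belief at
    each unit time — the raw material for parameter-recovery and
    variance-decay comparisons against the closed-form trajectory.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    engine = _LearningEngine(env, x0, omega, k, rng)
    X = np.empty((T + 1, len(x0)))
    X[0] = engine.effective_x()
    for t in range(1, T + 1):
        engine.unit_time()
        X[t] = engine.effective_x()
    return np.arange(T + 1), X


def simulate_population(cfg: PopulationConfig) -> TrajectoryRecord:
    """Run a full population experiment; bit-reproducible from the seed.

    Environment draws are independent across agents (shared statistics,
    not shared realizations).  Aggregate statistics are computed at
    every unit time; full per-agent snapshots are kept every
    ``record_every`` unit times.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_bets = (np.random.default_rng(c) for c in ss.spawn(2))
    x0 = _initial_x(cfg, rng_init)

    T, N = cfg.T, cfg.N
    snap_times = sorted(set(range(0, T + 1, cfg.record_every)) | {0, T})
    snap_times = np.asarray(snap_times, dtype=int)

    if cfg.learning:
        engine = _LearningEngine(cfg.env, x0, cfg.omega, cfg.k, rng_bets)
        logr = np.empty((T + 1, N))
        logr[0] = np.log(cfg.r0)
        x_by_time = np.empty((T + 1, N))
        x_by_time[0] = engine.effective_x()
        for t in range(1, T + 1):
            logr[t] = logr[t - 1] + engine.unit_time()
            x_by_time[t] = engine.effective_x()
    else:
        logr = _static_log_trajectories(cfg, x0, rng_bets)
        x_by_time = np.broadcast_to(x0, (T + 1, N))

    agg = _aggregate_table(logr, x_by_time)
    snap_idx = snap_times
    return TrajectoryRecord(
        times=np.arange(T + 1),
        snapshot_times=snap_times,
        resources=np.exp(logr[snap_idx]),
        x_values=np.array(x_by_time[snap_idx]),
        aggregates=agg,
        x_initial=x0,
        config=cfg,
    )


def _aggregate_table(logr: np.ndarray, x_by_time: np.ndarray) -> pd.DataFrame:
    T = logr.shape[0] - 1
    rows = []
    for t in range(T + 1):
        r = np.exp(logr[t])
        x = x_by_time[t]
        mean_g = float(np.mean((logr[t] - logr[0]) / t)) if t > 0 else np.nan
        rows.append(
            {
                "time": t,
                "mean_r": float(r.mean()),
                "var_r": float(r.var()),
                "gini": _metrics.gini(r),
                "cv": _metrics.coefficient_of_variation(r),
                "mean_x": float(x.mean()),
                "var_x": float(x.var()),
                "mean_G": mean_g,
            }
        )
    return pd.DataFrame(rows)


def time_averaged_growth(
    traj: TrajectoryRecord, gamma_ref: float, t: int | None = None
) -> GrowthConvergence:
    """Per-agent and population time-averaged growth at snapshot time t.

    ``G_i = (1/t) ln(r_i(t)/r_i(0))`` and the normalized gaps
    ``delta_i = (gamma_ref - G_i)/gamma_ref`` quantify convergence to
    the target rate; defaults to the final snapshot.
    """
    if t is None:
        t = int(traj.snapshot_times[-1])
    if t <= 0:
        raise ValueError("time-averaged growth requires t > 0")
    i0 = traj.snapshot_index(0)
    it = traj.snapshot_index(t)
    G = np.log(traj.resources[it] / traj.resources[i0]) / t
    mean_G = float(G.mean())
    return GrowthConvergence(
        t=float(t),
        G=G,
        mean_G=mean_G,
        delta=(gamma_ref - G) / gamma_ref,
        delta_mean=(gamma_ref - mean_G) / gamma_ref,
    )
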