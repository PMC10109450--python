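"""Inequality and heterogeneity statistics for resource populations.

The two headline inequality measures are the Gini coefficient, defined
through the normalized mean absolute pairwise difference

    G = sum_{i,j} |r_i - r_j| / (2 N^2 <r>),

and the coefficient of variation ``c_v = sigma_r / <r>``.  Both use the
population (1/N) convention; Gini runs from 0 (all equal) to
``(N-1)/N`` (one agent holds everything).

The growth-rate heterogeneity of a population decomposes, writing each
agent's rate as gamma_i = I_i - D_i (information minus divergence), as

    Var[gamma_i] = Var[I_i] + Var[D_i] - 2 Cov[I_i, D_i],

an exact algebraic identity.  Under Bayesian learning of a shared
environment the belief spread collapses hyperbolically,

    Var[x_i(t)] = sigma_x0^2 / (1 + t/(k l))^2,

i.e. asymptotically as t^-2, which is what drives the late-time decay of
growth-rate (and hence inequality) heterogeneity.
"""

from __future__ import annotations

from math import erf
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .infotheory import growth_rate_multinomial

if TYPE_CHECKING:  # pragma: no cover
    from .environment import EnvironmentSpec
    from .population import TrajectoryRecord

__all__ = [
    "gini",
    "coefficient_of_variation",
    "variance_decomposition",
    "x_variance_theory",
    "lognormal_gini_approx",
    "inequality_report",
]


def gini(resources) -> float:
    """Gini coefficient of a nonnegative resource vector.

    Uses the sorted-rank identity
    ``G = (2 sum_i i * r_(i)) / (N^2 <r>) - (N + 1)/N`` (ranks 1..N),
    equivalent to the pairwise mean-absolute-difference definition but
    O(N log N).  Scale-invariant; 0 for a constant vector; requires a
    positive total.
    """
    r = np.asarray(resources, dtype=float)
    if r.size == 0:
        raise ValueError("resources must be nonempty")
    if np.any(r < 0):
        raise ValueError("resources must be nonnegative")
    total = r.sum()
    if total <= 0:
        raise ValueError("Gini undefined for an all-zero population")
    n = r.size
    r = np.sort(r)
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks * r).sum() / (n * total) - (n + 1.0) / n)


def coefficient_of_variation(resources) -> float:
    """Population standard deviation over mean, c_v = sigma_r / <r>."""
    r = np.asarray(resources, dtype=float)
    if r.size == 0:
        raise ValueError("resources must be nonempty")
    mean = r.mean()
    if mean <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return float(r.std() / mean)


def variance_decomposition(I_values, D_values) -> tuple[float, float, float, float]:
    """Decompose Var[gamma_i] for gamma_i = I_i - D_i.

    Returns ``(var_I, var_D, covar, var_gamma)`` with the population
    (1/N) convention; ``var_gamma == var_I + var_D - 2*covar`` exactly.
    """
    I = np.asarray(I_values, dtype=float)
    D = np.asarray(D_values, dtype=float)
    if I.shape != D.shape or I.ndim != 1:
        raise ValueError("I and D must be 1-D sequences of equal length")
    if I.size < 2:
        raise ValueError("variance decomposition needs at least two agents")
    var_I = float(I.var())
    var_D = float(D.var())
    covar = float(((I - I.mean()) * (D - D.mean())).mean())
    var_gamma = float((I - D).var())
    return var_I, var_D, covar, var_gamma


def x_variance_theory(sigma_x0_sq: float, k: float, l: int, t) -> np.ndarray | float:
    """Closed-form belief-spread decay Var[x(t)] = sigma_x0^2/(1 + t/(kl))^2."""
    if sigma_x0_sq < 0:
        raise ValueError("sigma_x0_sq must be nonnegative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = sigma_x0_sq / (1.0 + t / (k * l)) ** 2
    return float(out) if out.ndim == 0 else out


def lognormal_gini_approx(sigma_log_r: float) -> float:
    """Gini of a lognormal resource distribution: erf(sigma / 2).

    ``sigma_log_r`` is the standard deviation of log resources; this is
    the standard closed form for lognormal populations such as the
    geometric-Brownian-motion limit of static-belief betting, where
    sigma grows as sigma_t * sqrt(t).
    """
    if sigma_log_r < 0:
        raise ValueError("sigma_log_r must be nonnegative")
    return erf(sigma_log_r / 2.0)


def inequality_report(traj: "TrajectoryRecord", env: "EnvironmentSpec") -> pd.DataFrame:
    """Time-indexed inequality table for a simulated trajectory.

    Per unit time: Gini, c_v, and Var[x] from the run's aggregates; the
    theoretical Var[x(t)] decay seeded by the run's initial belief
    spread; and, at snapshot times, the realized growth-rate variance
    Var[gamma(x_i(t))] from the closed-form rate.
    """
    agg = traj.aggregates
    k = traj.config.k
    theory = x_variance_theory(float(traj.x_initial.var()), k, env.l, agg["time"].to_numpy())
    out = agg[["time", "gini", "cv", "var_x"]].copy()
    out["theory_var_x"] = theory
    var_gamma = np.full(len(out), np.nan)
    for ti, t in enumerate(traj.snapshot_times):
        g = np.array([growth_rate_multinomial(env.l, env.p, x) for x in traj.x_values[ti]])
        var_gamma[out.index[out["time"] == t][0]] = g.var()
    out["var_gamma"] = var_gamma
    return out
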