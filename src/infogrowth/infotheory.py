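"""Information-theoretic growth quantities for proportional betting.

A bettor who observes a signal ``s`` and allocates a fraction ``B(e|s)``
of their resources to every possible event ``e`` grows, over many bets,
at the long-run rate

    gamma = sum_{e,s} P(s, e) log[ B(e|s) w_e ]      (nats per bet),

with ``w_e`` the payout for event ``e``.  Under fair odds
``w_e = 1/P(e)`` the rate decomposes as

    gamma = I(E; S) - E_s[ D_KL( P(E|s) || X(E|s) ) ],

where ``X(E|s)`` is the belief the allocation follows: mutual information
is the ceiling, and the expected KL divergence between truth and belief
is the price of ignorance.

For the degenerate multinomial environment parameterized by ``(l, p)``
and a belief of the same shape with diagonal ``x``, everything is closed
form:

    I(E;S)      = log l + p log p + (1-p) log[(1-p)/(l-1)]
    E_s[D_KL]   = p log(p/x) + (1-p) log[(1-p)/(1-x)]
    gamma(x)    = log l + p log x + (1-p) log[(1-x)/(l-1)]
    sigma(x)    = sqrt( p(1-p) ) * | log[ x(l-1)/(1-x) ] |

All quantities are stored in nats; ``nats_to_bits`` converts for display.
Impossible allocations are signalled with ±inf sentinels, never raised,
so parameter sweeps run to completion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import xlogy

from .environment import JointDistribution, fair_odds

__all__ = [
    "GrowthSummary",
    "growth_rate_general",
    "kelly_decomposition",
    "mutual_information_multinomial",
    "expected_kl_multinomial",
    "growth_rate_multinomial",
    "volatility_multinomial",
    "invert_growth_rate",
    "nats_to_bits",
]

LN2 = math.log(2.0)


def nats_to_bits(value: float) -> float:
    return value / LN2


@dataclass(frozen=True)
class GrowthSummary:
    """Growth-rate decomposition under fair odds, all in nats per bet.

    ``gamma = mutual_info - expected_kl`` holds by construction;
    ``sigma`` is the standard deviation of the per-bet log return.
    """

    gamma: float
    sigma: float
    mutual_info: float
    expected_kl: float

    def as_dict(self, bits: bool = False) -> dict:
        d = {
            "gamma": self.gamma,
            "sigma": self.sigma,
            "mutual_info": self.mutual_info,
            "expected_kl": self.expected_kl,
        }
        if bits:
            d = {k: nats_to_bits(v) for k, v in d.items()}
        return d


def growth_rate_general(
    joint: JointDistribution,
    policy: np.ndarray,
    odds: np.ndarray | None = None,
) -> float:
    """Long-run growth rate of a fixed allocation policy, in nats per bet.

    Parameters
    ----------
    joint
        Joint law P(e, s), events on rows.
    policy
        Allocation matrix B(e|s) with one column per signal, columns
        summing to 1.
    odds
        Payout per event; defaults to fair odds for a uniform marginal
        of the joint's event-alphabet size.

    Returns ``-inf`` when the policy puts zero mass on an event/signal
    pair of positive probability.
    """
    P = joint.matrix
    B = np.asarray(policy, dtype=float)
    if B.shape != P.shape:
        raise ValueError(f"policy shape {B.shape} does not match joint shape {P.shape}")
    if np.any(B < 0):
        raise ValueError("allocations must be nonnegative")
    colsums = B.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-9):
        raise ValueError("each per-signal allocation column must sum to 1")
    w = fair_odds(joint.n_events) if odds is None else np.asarray(odds, dtype=float)
    if w.shape != (joint.n_events,):
        raise ValueError(f"odds must have shape ({joint.n_events},)")
    if np.any(w <= 0):
        raise ValueError("odds must be strictly positive")
    with np.errstate(divide="ignore"):
        terms = xlogy(P, B * w[:, None])
    return float(terms.sum())


def kelly_decomposition(joint: JointDistribution, belief_conditional: np.ndarray) -> GrowthSummary:
    """Decompose the fair-odds growth rate of a belief X(E|S).

    ``belief_conditional`` has one column per signal, columns summing
    to 1.  Returns mutual information, the signal-averaged KL divergence
    D_KL(P(E|s) || X(E|s)), their difference gamma, and the per-bet log
    return standard deviation sigma.  A belief with zero mass where the
    truth has support yields ``expected_kl = +inf`` and ``gamma = -inf``.
    """
    P = joint.matrix
    X = np.asarray(belief_conditional, dtype=float)
    if X.shape != P.shape:
        raise ValueError(f"belief shape {X.shape} does not match joint shape {P.shape}")
    if np.any(X < 0) or not np.allclose(X.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("belief columns must be distributions over events")

    pe = joint.event_marginal()
    ps = joint.signal_marginal()
    cond = joint.conditional_given_signal()

    with np.errstate(divide="ignore", invalid="ignore"):
        mi = float(xlogy(P, P / np.outer(pe, ps)).sum())
        # E_s[D_KL] = sum_s P(s) sum_e P(e|s) log(P(e|s)/X(e|s))
        ekl = float((xlogy(P, cond) - xlogy(P, X)).sum())
    if math.isinf(ekl):
        ekl = math.inf
        gamma = -math.inf
        sigma = math.inf
    else:
        gamma = mi - ekl
        w = fair_odds(joint.n_events)
        with np.errstate(divide="ignore"):
            logret = np.where(X > 0, np.log(np.where(X > 0, X, 1.0) * w[:, None]), -np.inf)
        second = float((P * np.where(P > 0, logret**2, 0.0)).sum())
        sigma = math.sqrt(max(second - gamma**2, 0.0))
    return GrowthSummary(gamma=gamma, sigma=sigma, mutual_info=mi, expected_kl=ekl)


def _check_lp(l: int, p: float) -> None:
    if l < 2:
        raise ValueError(f"l must be >= 2, got {l}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")


def mutual_information_multinomial(l: int, p: float) -> float:
    """I(E;S) for the degenerate multinomial channel, in nats.

    Continuous at the endpoints via the 0*log(0) = 0 convention:
    0 at p = 1/l (independence), log l at p = 1 (noiseless channel).
    """
    _check_lp(l, p)
    t1 = p * math.log(p) if p > 0 else 0.0
    t2 = (1 - p) * math.log((1 - p) / (l - 1)) if p < 1 else 0.0
    return math.log(l) + t1 + t2


def expected_kl_multinomial(l: int, p: float, x: float) -> float:
    """Signal-averaged KL divergence between the true channel f(p,l) and
    a same-shaped belief f(x,l); nonnegative, zero iff x == p.

    Returns ``+inf`` for x in {0, 1} when the corresponding true mass is
    positive.
    """
    _check_lp(l, p)
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"x must lie in [0, 1], got {x}")
    if (x == 0.0 and p > 0.0) or (x == 1.0 and p < 1.0):
        return math.inf
    t1 = p * math.log(p / x) if p > 0 else 0.0
    t2 = (1 - p) * math.log((1 - p) / (1 - x)) if p < 1 else 0.0
    return t1 + t2


def growth_rate_multinomial(l: int, p: float, x: float) -> float:
    """Closed-form growth rate gamma(x) = log l + p log x + (1-p) log[(1-x)/(l-1)].

    Maximized at x = p where it equals I(E;S); zero at x = 1/l; ``-inf``
    at the endpoints x in {0, 1}.
    """
    _check_lp(l, p)
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"x must lie in [0, 1], got {x}")
    if (x == 0.0 and p > 0.0) or (x == 1.0 and p < 1.0):
        return -math.inf
    t1 = p * math.log(x) if p > 0 else 0.0
    t2 = (1 - p) * math.log((1 - x) / (l - 1)) if p < 1 else 0.0
    return math.log(l) + t1 + t2


def volatility_multinomial(l: int, p: float, x: float) -> float:
    """Per-bet log-return standard deviation sigma(x), in nats.

    sigma = sqrt(p(1-p)) * |log[x(l-1)/(1-x)]|: zero at x = 1/l (the
    uniform allocation cancels fair odds exactly), growing without bound
    toward either endpoint.
    """
    _check_lp(l, p)
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"x must lie in [0, 1], got {x}")
    if x in (0.0, 1.0):
        return math.inf
    return math.sqrt(p * (1 - p)) * abs(math.log(x * (l - 1) / (1 - x)))


def _upper_root(l: int, p: float) -> float:
    """The nontrivial zero of gamma(x) above p (the aggressive boundary)."""
    hi = 1.0 - 1e-12
    if growth_rate_multinomial(l, p, hi) >= 0:  # pragma: no cover - p ~ 1 corner
        return hi
    return brentq(lambda x: growth_rate_multinomial(l, p, x), p, hi, xtol=1e-14)


def invert_growth_rate(l: int, p: float, gamma_target: float, branch: str = "conservative") -> float:
    """Solve gamma(x) = gamma_target for x on one monotone branch.

    ``gamma(x)`` rises from 0 at ``x = 1/l`` to I(E;S) at ``x = p`` and
    falls back through 0 at a larger root found numerically.  The
    *conservative* branch returns the solution in ``(1/l, p]`` (lower
    volatility); the *aggressive* branch the one in ``[p, x_upper)``.

    Raises for nonpositive targets and for targets above the mutual
    information (infeasible).
    """
    if branch not in ("conservative", "aggressive"):
        raise ValueError(f"branch must be 'conservative' or 'aggressive', got {branch!r}")
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    if p <= 1.0 / l:
        raise ValueError(
            "branch inversion requires an informative aligned channel (p > 1/l)"
        )
    mi = mutual_information_multinomial(l, p)
    if gamma_target <= 0.0:
        raise ValueError(f"gamma_target must be positive, got {gamma_target}")
    if gamma_target > mi + 1e-15:
        raise ValueError(f"gamma_target {gamma_target} exceeds the mutual information {mi}")
    if gamma_target >= mi - 1e-15:
        return p

    f = lambda x: growth_rate_multinomial(l, p, x) - gamma_target
    eps = 1e-9
    if branch == "conservative":
        lo, hi = 1.0 / l + eps, p
    else:
        lo, hi = p, _upper_root(l, p) - eps
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16))
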