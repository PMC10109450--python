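"""Sequential Bayesian belief updating for the multinomial environment.

An agent models the signal-given-event channel as a categorical
likelihood with parameters ``beta[s, e]`` and the event marginal as a
Dirichlet-categorical with uniform pseudo-counts ``alpha_e = 1``.  The
likelihood parameters are initialized to the degenerate pattern
``f(x0, l)`` (diagonal ``x0``), and evidence enters through raw
(signal, event) count matrices.  The posterior conditional used for
allocation after observing counts ``m`` is

    X(e | s)  propto  ( m[s,e]/(omega*k) + beta[s,e] )
                      / ( M_s/(omega*k) + 1 )  *  ( n_e + alpha_e ),

normalized over events, where ``M_s`` and ``n_e`` are the signal and
event totals.  The inference time ``k`` (time per update) weighs the
evidence against the prior: counts accrue at ``omega`` observations per
unit time, so after ``t`` unit times each signal carries evidence weight
``t/(k*l)`` relative to the prior's weight of 1.  ``k -> inf`` freezes
the prior; ``k -> 0`` reduces to maximum likelihood.

Averaging the posterior diagonal recovers the agent's effective
diagonal-belief parameter ``x(t)``, whose ensemble mean follows the
closed form

    x(t) = ( p * t/(k*l) + x0 ) / ( 1 + t/(k*l) ),

a hyperbolic relaxation from the initial guess ``x0`` to the true
diagonal probability ``p`` in the dimensionless learning time
``lambda = t/(k*l)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BeliefState",
    "init_belief",
    "update_belief",
    "posterior_conditional",
    "effective_x",
    "x_trajectory_closed_form",
]


@dataclass(frozen=True)
class BeliefState:
    """Dirichlet-categorical posterior state of one agent.

    Attributes
    ----------
    l
        Alphabet size.
    alpha
        Event-marginal pseudo-counts (length ``l``; default all ones).
    beta
        Likelihood parameter matrix ``beta[s, e]``, rows summing to 1,
        held at its initialized degenerate ``f(x0, l)`` pattern.
    m
        Integer (signal, event) observation counts, ``m[s, e]``.
    k
        Inference time, time per update (> 0).
    omega
        Observations per unit time (>= 1).
    x0
        Initial diagonal belief parameter.
    """

    l: int
    alpha: np.ndarray
    beta: np.ndarray
    m: np.ndarray
    k: float
    omega: float
    x0: float

    @property
    def n(self) -> np.ndarray:
        """Event counts n_e (column sums of m)."""
        return self.m.sum(axis=0)

    @property
    def M(self) -> np.ndarray:
        """Signal counts M_s (row sums of m)."""
        return self.m.sum(axis=1)

    @property
    def n_updates(self) -> int:
        return int(self.m.sum())

    def to_json(self) -> str:
        """Serialize counts and hyperparameters for checkpointing."""
        return json.dumps(
            {
                "l": self.l,
                "alpha": self.alpha.tolist(),
                "beta": self.beta.tolist(),
                "m": self.m.tolist(),
                "k": self.k,
                "omega": self.omega,
                "x0": self.x0,
                "effective_x": effective_x(self),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "BeliefState":
        d = json.loads(payload)
        return cls(
            l=int(d["l"]),
            alpha=np.asarray(d["alpha"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            m=np.asarray(d["m"], dtype=np.int64),
            k=float(d["k"]),
            omega=float(d["omega"]),
            x0=float(d["x0"]),
        )


def degenerate_pattern(l: int, x: float) -> np.ndarray:
    """The l-by-l matrix f(x, l): ``x`` on the diagonal, rows summing to 1."""
    m = np.full((l, l), (1.0 - x) / (l - 1))
    np.fill_diagonal(m, x)
    return m


def init_belief(l: int, x0: float, k: float = 1.0, omega: float = 100.0) -> BeliefState:
    """Fresh belief with zero counts and a degenerate f(x0, l) likelihood.

    ``x0`` below ``1/l`` (an anti-aligned prior) is accepted but outside
    the aligned-channel regime the closed-form trajectory targets.
    """
    if l < 2:
        raise ValueError(f"l must be >= 2, got {l}")
    if not (0.0 < x0 < 1.0):
        raise ValueError(f"x0 must lie in (0, 1), got {x0}")
    if k <= 0:
        raise ValueError(f"inference time k must be positive, got {k}")
    if omega < 1:
        raise ValueError(f"omega must be >= 1, got {omega}")
    return BeliefState(
        l=l,
        alpha=np.ones(l),
        beta=degenerate_pattern(l, x0),
        m=np.zeros((l, l), dtype=np.int64),
        k=float(k),
        omega=float(omega),
        x0=float(x0),
    )


def update_belief(belief: BeliefState, s: int, e: int) -> BeliefState:
    """Record one observed (signal, event) pair; labels are 1-based.

    Returns a new state with ``m[s, e]`` incremented.  The prior
    parameters never move: evidence enters the posterior only through
    the counts, scaled by ``1/(omega*k)`` at evaluation time.
    """
    if not (1 <= s <= belief.l) or not (1 <= e <= belief.l):
        raise IndexError(f"state labels must lie in 1..{belief.l}, got s={s}, e={e}")
    m = belief.m.copy()
    m[s - 1, e - 1] += 1
    return replace(belief, m=m)


def posterior_conditional(belief: BeliefState, s: int) -> np.ndarray:
    """Posterior event distribution X(E|s) for 1-based signal ``s``.

    Nonnegative and normalized; reduces to the ``f(x0, l)`` prior row
    when no evidence has been observed.
    """
    if not (1 <= s <= belief.l):
        raise IndexError(f"signal label must lie in 1..{belief.l}, got {s}")
    si = s - 1
    wk = belief.omega * belief.k
    num = (belief.m[si] / wk + belief.beta[si]) / (belief.M[si] / wk + 1.0)
    num = num * (belief.n + belief.alpha)
    return num / num.sum()


def effective_x(belief: BeliefState) -> float:
    """Diagonal-average belief parameter x(t) = (1/l) sum_s X(s|s)."""
    return float(
        np.mean([posterior_conditional(belief, s)[s - 1] for s in range(1, belief.l + 1)])
    )


def x_trajectory_closed_form(p: float, x0: float, k: float, l: int, t) -> np.ndarray | float:
    """Ensemble-mean belief trajectory x(t) = (p*t/(kl) + x0)/(1 + t/(kl)).

    Accepts scalar or array ``t >= 0``; monotone from ``x0`` at ``t = 0``
    toward ``p`` as ``t -> inf``, halfway at ``t = k*l``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    lam = t / (k * l)
    out = (p * lam + x0) / (1.0 + lam)
    return float(out) if out.ndim == 0 else out
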