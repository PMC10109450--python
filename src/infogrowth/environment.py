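"""Stationary degenerate-multinomial environments.

The environment emits, at every betting step, a hidden event ``e`` and a
private signal ``s``, both drawn from the same alphabet ``{1, ..., l}``.
The channel between them is the degenerate multinomial conditional

    P(e | s) = p            if e == s,
    P(e | s) = (1 - p)/(l - 1)   otherwise,

with uniform marginals P(e) = P(s) = 1/l, so that the conditional is
symmetric: P(e|s) = P(s|e).  ``p`` is the probability that the signal
points at the correct event; ``p = 1/l`` makes signal and event
independent, ``p -> 1`` makes the signal a perfect predictor.

State labels are 1-based (``1..l``) at every public boundary; arrays are
indexed 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentSpec",
    "JointDistribution",
    "conditional_prob",
    "conditional_matrix",
    "to_joint",
    "fair_odds",
    "sample_step",
    "sample",
]

_ATOL = 1e-12


def fair_odds(l: int) -> np.ndarray:
    """Fair payout vector ``w_e = 1/P(e) = l`` for a uniform event marginal."""
    return np.full(l, float(l))


@dataclass(frozen=True)
class EnvironmentSpec:
    """Degenerate multinomial (event, signal) environment.

    Parameters
    ----------
    l
        Alphabet size shared by events and signals; ``l >= 2``.
    p
        Diagonal conditional probability ``P(e = s | s)``, in ``(0, 1)``.
    odds
        Payout factor per event.  Defaults to fair odds ``w_e = l``.
    """

    l: int
    p: float
    odds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if int(self.l) != self.l or self.l < 2:
            raise ValueError(f"alphabet size l must be an integer >= 2, got {self.l}")
        object.__setattr__(self, "l", int(self.l))
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"diagonal probability p must lie in (0, 1), got {self.p}")
        odds = fair_odds(self.l) if self.odds is None else np.asarray(self.odds, dtype=float)
        if odds.shape != (self.l,):
            raise ValueError(f"odds must have shape ({self.l},), got {odds.shape}")
        if np.any(odds <= 0):
            raise ValueError("odds must be strictly positive")
        odds.setflags(write=False)
        object.__setattr__(self, "odds", odds)

    @property
    def off_diagonal(self) -> float:
        """Conditional probability of each of the ``l - 1`` wrong events."""
        return (1.0 - self.p) / (self.l - 1)


@dataclass(frozen=True)
class JointDistribution:
    """Joint law P(e, s): rows are events, columns are signals."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("joint distribution must be a 2-D matrix")
        if np.any(m < 0):
            raise ValueError("joint probabilities must be nonnegative")
        if abs(m.sum() - 1.0) > _ATOL:
            raise ValueError(f"joint probabilities must sum to 1, got {m.sum()!r}")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_signals(self) -> int:
        return self.matrix.shape[1]

    def event_marginal(self) -> np.ndarray:
        """P(e): row sums."""
        return self.matrix.sum(axis=1)

    def signal_marginal(self) -> np.ndarray:
        """P(s): column sums."""
        return self.matrix.sum(axis=0)

    def conditional_given_signal(self) -> np.ndarray:
        """P(e|s) as a matrix with columns summing to 1."""
        ps = self.signal_marginal()
        if np.any(ps <= 0):
            raise ValueError("conditional undefined for zero-probability signals")
        return self.matrix / ps[None, :]

    def to_csv(self, path_or_buf) -> None:
        """Write as a plain CSV matrix with 1-based signal labels as header."""
        df = pd.DataFrame(
            self.matrix,
            index=np.arange(1, self.n_events + 1),
            columns=[f"s{j}" for j in range(1, self.n_signals + 1)],
        )
        df.to_csv(path_or_buf, index_label="event", float_format="%.17g")

    @classmethod
    def from_csv(cls, path_or_buf) -> "JointDistribution":
        df = pd.read_csv(path_or_buf, index_col=0, float_precision="round_trip")
        return cls(df.to_numpy(dtype=float))


def conditional_prob(env: EnvironmentSpec, e: int, s: int) -> float:
    """P(e | s) for 1-based state labels ``e, s`` in ``1..l``."""
    if not (1 <= e <= env.l) or not (1 <= s <= env.l):
        raise IndexError(f"state labels must lie in 1..{env.l}, got e={e}, s={s}")
    return env.p if e == s else env.off_diagonal


def conditional_matrix(env: EnvironmentSpec) -> np.ndarray:
    """The full l-by-l matrix P(e|s): ``p`` on the diagonal, symmetric."""
    m = np.full((env.l, env.l), env.off_diagonal)
    np.fill_diagonal(m, env.p)
    return m


def to_joint(env: EnvironmentSpec) -> JointDistribution:
    """Joint law P(e, s) = P(e|s)/l induced by the uniform signal marginal."""
    return JointDistribution(conditional_matrix(env) / env.l)


def sample_step(env: EnvironmentSpec, rng: np.random.Generator) -> tuple[int, int]:
    """Draw one (event, signal) pair with 1-based labels.

    The event is uniform on ``1..l``; the signal equals the event with
    probability ``p`` and is otherwise uniform over the remaining labels
    (the symmetric channel makes sampling e then s|e equivalent to
    sampling s then e|s).
    """
    e, s = sample(env, 1, rng)
    return int(e[0]), int(s[0])


def sample(env: EnvironmentSpec, size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``size`` iid (event, signal) pairs; returns 1-based label arrays."""
    e = rng.integers(0, env.l, size=size)
    hit = rng.random(size) < env.p
    # a miss lands uniformly on one of the other l-1 labels
    offset = rng.integers(1, env.l, size=size)
    s = np.where(hit, e, (e + offset) % env.l)
    return e + 1, s + 1
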