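"""Two-state Markov chain of good/bad feeding environments.

The environment alternates between a good state (feeding level ``EY_high``)
and a bad state (``EY_low``) according to switch probabilities ``p`` (good
to bad) and ``q`` (bad to good).  Two derived descriptors summarise a
regime: the serial autocorrelation ``rho = 1 - p - q`` (positive: red,
persistent noise; zero: white; negative: blue, alternating noise) and the
stationary frequency of the good state ``f = q / (p + q)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GOOD",
    "BAD",
    "FeedingRegime",
    "transition_matrix",
    "autocorrelation",
    "good_state_frequency",
    "simulate_state_sequence",
    "export_state_sequence",
]

#: External state encoding: state 1 is the good environment, state 2 the bad.
GOOD = 1
BAD = 2


@dataclass(frozen=True)
class FeedingRegime:
    """A stochastic feeding environment specification.

    ``EY_low == EY_high`` is permitted and yields a degenerate (constant)
    environment, useful as a deterministic cross-check.
    """

    p: float
    q: float
    EY_low: float
    EY_high: float
    sigma_Y: float

    def __post_init__(self) -> None:
        for name in ("p", "q"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.EY_low <= self.EY_high <= 1.0):
            raise ValueError(
                f"feeding levels must satisfy 0 <= EY_low <= EY_high <= 1, "
                f"got ({self.EY_low}, {self.EY_high})"
            )
        if self.sigma_Y < 0:
            raise ValueError("sigma_Y must be >= 0")

    @property
    def rho(self) -> float:
        return autocorrelation(self)

    @property
    def f(self) -> float:
        return good_state_frequency(self)

    def feeding_level(self, state: int) -> float:
        if state == GOOD:
            return self.EY_high
        if state == BAD:
            return self.EY_low
        raise ValueError(f"unknown environment state {state}")


def transition_matrix(regime: FeedingRegime) -> np.ndarray:
    """Column-stochastic habitat transition matrix [[1-p, q], [p, 1-q]].

    Column 1 is the good state, column 2 the bad state; entry (i, j) is the
    probability of moving to state i given state j.
    """
    return np.array([[1.0 - regime.p, regime.q], [regime.p, 1.0 - regime.q]])


def autocorrelation(regime: FeedingRegime) -> float:
    """Serial (lag-1) autocorrelation of the chain, ``rho = 1 - p - q``."""
    return 1.0 - regime.p - regime.q


def good_state_frequency(regime: FeedingRegime) -> float:
    """Stationary probability of the good state, ``f = q / (p + q)``."""
    if regime.p + regime.q == 0.0:
        raise ValueError(
            "good-state frequency is undefined for p = q = 0 (frozen chain)"
        )
    return regime.q / (regime.p + regime.q)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_sequence(regime: FeedingRegime, length: int, seed) -> np.ndarray:
    """Simulate a state sequence (values :data:`GOOD` = 1, :data:`BAD` = 2).

    The initial state is drawn uniformly at random; each subsequent state
    follows the transition matrix.  Reproducible under a fixed seed
    (``seed`` may be an int, a ``SeedSequence`` or a ``Generator``).
    """
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    rng = _as_rng(seed)
    draws = rng.random(length)
    states = np.empty(length, dtype=np.int8)
    good = draws[0] < 0.5  # uniform initial state
    states[0] = GOOD if good else BAD
    p, q = regime.p, regime.q
    for t in range(1, length):
        if good:
            good = draws[t] >= p
        else:
            good = draws[t] < q
        states[t] = GOOD if good else BAD
    return states


def export_state_sequence(states: np.ndarray, path) -> None:
    """Write a simulated sequence as a two-column (time, state) TSV."""
    table = np.column_stack([np.arange(len(states)), states])
    np.savetxt(path, table, fmt="%d", delimiter="\t", header="time\tstate")
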