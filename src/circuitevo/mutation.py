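"""Mutation lattice over a circuit's mutable promoters.

Each strain is identified by a tuple of *functional levels*, one per
mutable promoter, drawn from {100, 67, 33, 0} percent of the designed
maximal transcription rate.  Mutation moves a strain down the lattice:
only function-reducing changes are allowed, only one promoter can change
per event, and larger level jumps are geometrically less likely.  The
resulting directed rate matrix is used by the population simulator as a
continuous first-order transfer term between strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "LEVELS",
    "MutationState",
    "MutationScheme",
    "enumerate_states",
    "transition_rate",
    "build_transition_matrix",
]

#: Functional levels (% of designed maximal transcription rate), in the
#: documented descending order used for state enumeration.
LEVELS: tuple[int, ...] = (100, 67, 33, 0)

MutationState = tuple[int, ...]


def enumerate_states(n_promoters: int) -> list[MutationState]:
    """All ``4**n`` mutation states in lexicographic descending-level order.

    The first state is the fully functional design ``(100, ..., 100)`` and
    the last is the fully non-functional absorbing state ``(0, ..., 0)``.
    """
    if n_promoters not in (1, 2, 3):
        raise ValueError(
            f"mutable promoter count must be 1, 2 or 3, got {n_promoters}")
    return [tuple(t) for t in product(LEVELS, repeat=n_promoters)]


def transition_rate(state_from: MutationState, state_to: MutationState,
                    base_rate: float = 1e-5,
                    attenuation: float = 0.1) -> float:
    """Mutation rate (1/min) for the transition ``state_from -> state_to``.

    Zero unless exactly one promoter changes and its level strictly
    decreases; a single-level drop occurs at ``base_rate`` and each extra
    level skipped multiplies the rate by ``attenuation``.
    """
    if len(state_from) != len(state_to):
        raise ValueError("mutation states live on different lattices")
    if base_rate < 0 or not 0 < attenuation <= 1:
        raise ValueError("need base_rate >= 0 and 0 < attenuation <= 1")
    changed = [(a, b) for a, b in zip(state_from, state_to) if a != b]
    if len(changed) != 1:
        return 0.0
    a, b = changed[0]
    if b > a:                      # function-increasing: forbidden
        return 0.0
    jump = LEVELS.index(b) - LEVELS.index(a)
    return base_rate * attenuation ** (jump - 1)


def build_transition_matrix(states: list[MutationState],
                            base_rate: float = 1e-5,
                            attenuation: float = 0.1) -> np.ndarray:
    """Dense rate matrix ``M[i, j] = rate(state_i -> state_j)``.

    The fully non-functional state has an all-zero row (absorbing).
    """
    n = len(states)
    M = np.zeros((n, n))
    for i, si in enumerate(states):
        for j, sj in enumerate(states):
            if i != j:
                M[i, j] = transition_rate(si, sj, base_rate, attenuation)
    return M


@dataclass(frozen=True)
class MutationScheme:
    """Enumerated lattice plus its transition-rate structure.

    ``base_rate`` (1/min) is the rate of a single-level drop at one
    promoter; ``attenuation`` scales the rate down per extra level skipped.
    """

    n_promoters: int
    base_rate: float = 1e-5
    attenuation: float = 0.1
    states: list[MutationState] = field(init=False)
    matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        states = enumerate_states(self.n_promoters)
        object.__setattr__(self, "states", states)
        object.__setattr__(
            self, "matrix",
            build_transition_matrix(states, self.base_rate, self.attenuation))

    @property
    def n_states(self) -> int:
        return len(self.states)

    def levels_fraction(self) -> np.ndarray:
        """(n_states, n_promoters) array of levels as fractions in [0, 1]."""
        return np.array(self.states, dtype=float) / 100.0

    def ancestral_index(self) -> int:
        return self.states.index(tuple([100] * self.n_promoters))

    def to_frame(self):
        """Rate matrix as a labelled DataFrame (for CSV audit output)."""
        import pandas as pd
        labels = ["/".join(map(str, s)) for s in self.states]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)
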