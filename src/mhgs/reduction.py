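"""Linear population-size reduction.

A large population explores well early; a small one converges fast late.
The schedule shrinks the agent count linearly in the number of function
evaluations spent, from ``np_max`` at FE = 0 down to ``np_min`` at the
budget. Removal is elitist: the worst-fitness agents go first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReductionPolicy", "next_population_size", "shrink_population"]


@dataclass
class ReductionPolicy:
    """Linear reduction schedule parameters."""

    np_max: int = 100
    np_min: int = 30
    max_fe: int = 45000

    def __post_init__(self):
        if self.np_min < 2:
            raise ValueError("np_min must be >= 2")
        if self.np_min > self.np_max:
            raise ValueError("np_min must not exceed np_max")
        if self.max_fe <= 0:
            raise ValueError("max_fe must be positive")


def next_population_size(fe: int, policy: ReductionPolicy) -> int:
    """Target size NP = round((NP_min - NP_max)/MAX_FE · FE + NP_max).

    Monotone non-increasing in FE with NP(0) = NP_max and
    NP(MAX_FE) = NP_min.
    """
    if not (0 <= fe <= policy.max_fe):
        raise ValueError("fe must lie in [0, max_fe]")
    slope = (policy.np_min - policy.np_max) / policy.max_fe
    return int(np.rint(slope * fe + policy.np_max))


def shrink_population(pop, target: int) -> None:
    """Drop the worst agents in place until ``pop.size == target``.

    Survivors are the ``target`` best-fitness agents; among equal-fitness
    candidates the hungrier agent is removed first, then the lower index.
    The incumbent-best agent is never removed (it has the minimal fitness of
    the generation by construction).
    """
    if target < 2:
        raise ValueError("target population size must be >= 2")
    if target > pop.size:
        raise ValueError("cannot grow the population by shrinking")
    if target == pop.size:
        return
    n = pop.size
    # lexsort keys in reverse order of priority: fitness asc, hunger asc
    # (hungrier removed first), index desc (lower index removed first).
    order = np.lexsort((-np.arange(n), pop.hunger, pop.fitness))
    keep = np.sort(order[:target])
    pop.positions = pop.positions[keep]
    pop.fitness = pop.fitness[keep]
    pop.hunger = pop.hunger[keep]
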