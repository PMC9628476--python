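"""Centroid-based fuzzy mutation.

The mutation probability of an agent is a fuzzy combination of two
membership degrees: how close the agent sits to the population centroid
(crowded agents are more likely to be mutated) and how long the global best
has stagnated (longer stagnation raises mutation pressure everywhere). A
fired mutation perturbs every coordinate by at most a step bound that decays
quadratically over the evaluation budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rng import RandomStream
from .space import SearchSpace, clamp_to_bounds

__all__ = [
    "FuzzyMutationParams",
    "MutationDecision",
    "distance_contribution",
    "history_contribution",
    "mutation_probability",
    "mutation_step",
    "propose_mutations",
    "apply_fuzzy_mutation",
]


@dataclass
class FuzzyMutationParams:
    """Settings of the fuzzy mutation operator.

    ``alpha_h`` and ``beta_h`` shape the stagnation membership function
    (P_c = a_mf + b_mf·tanh(unchanged/alpha_h - beta_h)); ``rho`` and
    ``phi`` weight the distance and history contributions in the combined
    probability. Defaults follow the mHGS settings (alpha_h=4, beta_h=5,
    a_mf=b_mf=0.5, rho=0.6, phi=0.4).
    """

    alpha_h: float = 4.0
    beta_h: float = 5.0
    a_mf: float = 0.5
    b_mf: float = 0.5
    rho: float = 0.6
    phi: float = 0.4
    normalize_dist: bool = True

    def __post_init__(self):
        for name in ("alpha_h", "beta_h", "a_mf", "b_mf", "rho", "phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MutationDecision:
    """Record of one agent's mutation draw."""

    p_distance: float
    p_history: float
    p_mutation: float
    delta_q: np.ndarray
    fired: bool


def distance_contribution(position, centroid, space: SearchSpace,
                          params: FuzzyMutationParams) -> float:
    """P_d = 1/(1 + dist): membership degree of 'near the centroid'.

    ``dist`` is the Euclidean distance from the agent to the population
    centroid, normalized by the box diagonal when ``normalize_dist`` is on
    so that P_d is comparable across search spaces of different scale. The
    +1 in the denominator keeps the degree finite (exactly 1) for an agent
    sitting on the centroid.
    """
    dist = float(np.linalg.norm(np.asarray(position, float) - centroid))
    if params.normalize_dist and space.diagonal > 0:
        dist /= space.diagonal
    return 1.0 / (1.0 + dist)


def history_contribution(unchanged: int, params: FuzzyMutationParams) -> float:
    """P_c = a + b·tanh(unchanged/alpha - beta): stagnation membership.

    Strictly increasing in the stagnation counter, ~0 for a freshly
    improving search, 0.5 at unchanged = alpha·beta generations, saturating
    toward 1 under prolonged stagnation.
    """
    if unchanged < 0:
        raise ValueError("unchanged must be >= 0")
    return params.a_mf + params.b_mf * np.tanh(
        unchanged / params.alpha_h - params.beta_h)


def mutation_probability(p_distance: float, p_history: float,
                         params: FuzzyMutationParams) -> float:
    """Combined probability P_l = rho·P_d + phi·P_c.

    History gets the lower weight (phi = 0.4 by default): other agents keep
    moving even when the best stalls, so crowding is the stronger signal.
    """
    return params.rho * p_distance + params.phi * p_history


def mutation_step(range_j, count: int, iter_total: int):
    """Step bound Δq = 0.5·range·(1 - count/iter_total)², per dimension.

    ``count`` is the progress index (function evaluations spent) and
    ``iter_total`` the total budget; the bound shrinks quadratically so late
    mutations only nudge agents.
    """
    if iter_total <= 0:
        raise ValueError("iter_total must be positive")
    if not (0 <= count <= iter_total):
        raise ValueError("count must lie in [0, iter_total]")
    return 0.5 * np.asarray(range_j, dtype=float) * (1.0 - count / iter_total) ** 2


def propose_mutations(pop, space: SearchSpace, params: FuzzyMutationParams,
                      count: int, iter_total: int,
                      rng: RandomStream) -> tuple[np.ndarray, list[MutationDecision]]:
    """Draw mutation candidates for the population (no acceptance).

    One uniform draw u per agent gates the mutation (fired iff P_l > u).
    A fired agent's candidate moves by ±min(Δq_j, |X_ij|) in every
    dimension with an independent random sign, clamped to the bounds; a
    non-fired agent's candidate is its unchanged position. Returns the
    (n, dim) candidate array and one decision record per agent.
    """
    n = pop.size
    centroid = pop.positions.mean(axis=0)
    delta_q = mutation_step(space.range, count, iter_total)

    p_c = history_contribution(pop.unchanged, params)
    decisions: list[MutationDecision] = []
    u = rng.random(n)
    signs = rng.sign((n, space.dim))
    candidates = pop.positions.copy()
    for i in range(n):
        p_d = distance_contribution(pop.positions[i], centroid, space, params)
        p_l = mutation_probability(p_d, p_c, params)
        fired = bool(p_l > u[i])
        if fired:
            delta_p = np.minimum(delta_q, np.abs(pop.positions[i]))
            candidates[i] = pop.positions[i] + signs[i] * delta_p
        decisions.append(MutationDecision(p_d, float(p_c), float(p_l),
                                          delta_q, fired))
    return clamp_to_bounds(candidates, space), decisions


def apply_fuzzy_mutation(pop, space: SearchSpace, params: FuzzyMutationParams,
                         count: int, iter_total: int,
                         rng: RandomStream) -> list[MutationDecision]:
    """Mutate the population in place unconditionally (no selection).

    Convenience wrapper over :func:`propose_mutations` for inspecting the
    operator in isolation. The optimizer itself is greedy: it evaluates
    each fired candidate and keeps it only when it improves on the agent's
    current fitness (the new and previous solutions are compared and the
    better one is retained).
    """
    candidates, decisions = propose_mutations(pop, space, params, count,
                                              iter_total, rng)
    pop.positions = candidates
    return decisions
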