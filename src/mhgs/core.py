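"""The hunger games search (HGS) engine.

HGS is a population metaheuristic in which each agent carries a *hunger*
level that grows while the agent's fitness lags behind the incumbent best.
Hunger-derived weights (W1, W2) modulate how strongly agents are pulled
toward the best position, and a sech-shaped variation control E switches
agents between approaching and departing the incumbent. The engine here
implements the canonical update rules and exposes hooks for the two
modifications that define mHGS: centroid-based fuzzy mutation
(:mod:`mhgs.fuzzy`) and linear population reduction (:mod:`mhgs.reduction`).

All equation-level rules are plain functions that accept their random inputs
explicitly and broadcast over arrays; the main loop calls the same functions
with per-population vectors, so unit-level oracles exercise exactly the code
the optimizer runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .rng import RandomStream
from .space import SearchSpace, clamp_to_bounds

__all__ = [
    "HGSParams",
    "Agent",
    "Population",
    "RunResult",
    "variation_control",
    "shrink_factor",
    "hunger_weights",
    "hunger_increment",
    "position_update",
    "initialize_population",
    "optimize",
]


@dataclass
class HGSParams:
    """Engine settings.

    Attributes
    ----------
    n_agents : int
        Initial population size N (>= 2). Default 30.
    max_fe : int
        Function-evaluation budget MAX_FE. Default 45000.
    l : float
        Branch-switch probability in (0, 1); gates both the random
        self-scaling move and the hungry W1 branch. Default 0.03.
    lh : float
        Lower bound LH of the hunger increment. Default 100.
    """

    n_agents: int = 30
    max_fe: int = 45000
    l: float = 0.03
    lh: float = 100.0

    def __post_init__(self):
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if not (0.0 < self.l < 1.0):
            raise ValueError("l must be in (0, 1)")
        if self.lh <= 0:
            raise ValueError("lh must be positive")
        if self.max_fe < self.n_agents:
            raise ValueError("max_fe must allow at least one generation")


@dataclass
class Agent:
    """One candidate solution: position, fitness, hunger."""

    position: np.ndarray
    fitness: float
    hunger: float


@dataclass
class Population:
    """Agent collection plus global search bookkeeping.

    ``positions`` is an (n, dim) array; ``fitness`` and ``hunger`` are
    aligned (n,) vectors. ``best_fitness``/``best_position`` track the
    incumbent (best-so-far) solution, ``worst_fitness`` the worst of the
    current generation, ``unchanged`` the number of consecutive generations
    without strict improvement of the incumbent, and ``fe`` the evaluations
    spent.
    """

    positions: np.ndarray
    fitness: np.ndarray
    hunger: np.ndarray
    best_position: Optional[np.ndarray] = None
    best_fitness: float = np.inf
    worst_fitness: float = -np.inf
    unchanged: int = 0
    fe: int = 0

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    @property
    def hunger_sum(self) -> float:
        return float(self.hunger.sum())

    @property
    def agents(self) -> list[Agent]:
        return [
            Agent(self.positions[i].copy(), float(self.fitness[i]), float(self.hunger[i]))
            for i in range(self.size)
        ]


@dataclass
class RunResult:
    """Outcome of one optimization run."""

    best_fitness: float
    best_position: np.ndarray
    trace: list[tuple[int, float]]
    seed: int
    n_evaluations: int
    config: dict = field(default_factory=dict)
    cpu_seconds: float = 0.0
    mutation_log: list[dict] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "best_fitness": self.best_fitness,
            "best_position": np.asarray(self.best_position).tolist(),
            "trace": [[int(fe), float(bf)] for fe, bf in self.trace],
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
            "config": self.config,
            "cpu_seconds": self.cpu_seconds,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def trace_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fe,best_fitness\n")
            for fe, bf in self.trace:
                fh.write(f"{fe},{bf!r}\n")


# ---------------------------------------------------------------------------
# Equation-level rules
# ---------------------------------------------------------------------------

def variation_control(fitness, best_fitness):
    """Variation control E = sech(|F_i - BF|), in (0, 1].

    The hyperbolic secant maps fitness gaps to an exploitation gate: agents
    close to the incumbent get E near 1 (more likely to refine), distant
    agents get E near 0. Computed in an overflow-safe form.
    """
    fitness = np.asarray(fitness, dtype=float)
    if not (np.all(np.isfinite(fitness)) and np.isfinite(best_fitness)):
        raise ValueError("variation_control requires finite fitness values")
    x = np.abs(fitness - best_fitness)
    # sech(x) = 2 e^-x / (1 + e^-2x), stable for large x
    ex = np.exp(-x)
    out = 2.0 * ex / (1.0 + ex * ex)
    return out if out.ndim else float(out)


def shrink_factor(fe: int, max_fe: int) -> float:
    """Exploration radius a = 2(1 - FE/MAX_FE); the step R ~ U[-a, a]."""
    if max_fe <= 0:
        raise ValueError("max_fe must be positive")
    if not (0 <= fe <= max_fe):
        raise ValueError("fe must lie in [0, max_fe]")
    return 2.0 * (1.0 - fe / max_fe)


def hunger_weights(hunger, total_hunger, n_agents, l, r3, r4, r5):
    """Hunger weights (W1, W2) of an agent.

    W1 = hungry·N/SHungry·r4 when r3 < l (and 1 otherwise, or when the
    population carries no hunger at all); W2 = (1 - exp(-|hungry -
    SHungry|))·r5·2, always in [0, 2).

    The weights are per-coordinate quantities: ``r4`` and ``r5`` may be
    fresh uniform draws for every dimension of an agent (as the engine
    uses them), or scalars. All arguments broadcast.
    """
    hunger = np.asarray(hunger, dtype=float)
    r3 = np.asarray(r3, dtype=float)
    r4 = np.asarray(r4, dtype=float)
    r5 = np.asarray(r5, dtype=float)
    if total_hunger > 0:
        hungry_w1 = hunger * n_agents / total_hunger * r4
    else:
        hungry_w1 = np.ones_like(hunger * r4)
    w1 = np.where(r3 < l, hungry_w1, 1.0)
    w2 = (1.0 - np.exp(-np.abs(hunger - total_hunger))) * r5 * 2.0
    w2 = np.broadcast_arrays(w2, w1)[0]
    if w1.ndim == 0:
        return float(w1), float(w2)
    return w1, w2


def hunger_increment(fitness, best_fitness, worst_fitness, bounds_range, lh, r6, r):
    """Hunger increment H for a non-best agent.

    TH = (F - BF)/(WF - BF) · r6 · 2 · (UB - LB); H = LH·(1+r) when
    TH < LH, else TH. A flat generation (WF == BF) defines TH = 0, which
    forces the maximal-pressure branch H = LH·(1+r).
    ``bounds_range`` is the scalar search range (mean of UB - LB when bounds
    differ per dimension).
    """
    fitness = np.asarray(fitness, dtype=float)
    r6 = np.asarray(r6, dtype=float)
    r = np.asarray(r, dtype=float)
    span = worst_fitness - best_fitness
    if span > 0:
        th = (fitness - best_fitness) / span * r6 * 2.0 * bounds_range
    else:
        th = np.zeros_like(fitness)
    h = np.where(th < lh, lh * (1.0 + r), th)
    return float(h) if h.ndim == 0 else h


def position_update(x, x_best, w1, w2, r_step, e, l, r1, r2, z):
    """Propose new positions (unclamped).

    Three branches, chosen independently for every coordinate:
    r1 < l → self-scaling x·(1 + z) with z standard-normal; otherwise
    depart from (r2 > E) or approach (r2 < E) the incumbent:
    W1·Xb ± R·W2·|Xb - x|.

    ``x`` is a position (dim,) or a batch (n, dim); every other argument is
    a scalar or an array broadcastable against ``x`` (the engine draws
    r1, r2, z, W1, W2 per coordinate and R, E per agent).
    """
    x = np.asarray(x, dtype=float)
    gap = np.abs(x_best - x)
    step = np.asarray(r_step) * np.asarray(w2) * gap
    anchor = np.asarray(w1) * x_best
    move = np.where(np.asarray(r2) > np.asarray(e), anchor + step,
                    anchor - step)
    return np.where(np.asarray(r1) < l, x * (1.0 + np.asarray(z)), move)


# ---------------------------------------------------------------------------
# Initialization and the main loop
# ---------------------------------------------------------------------------

def initialize_population(space: SearchSpace, params: HGSParams,
                          rng: RandomStream) -> Population:
    """Uniform-random initial population X = LB + rand·(UB - LB).

    Hunger starts at zero; fitness is NaN until the first evaluation.
    """
    n = params.n_agents
    u = rng.random((n, space.dim))
    positions = space.lower + u * (space.upper - space.lower)
    return Population(
        positions=positions,
        fitness=np.full(n, np.nan),
        hunger=np.zeros(n),
    )


def _update_hunger_inplace(pop: Population, space: SearchSpace,
                           params: HGSParams, rng: RandomStream) -> None:
    """Vectorized hunger bookkeeping for the current generation."""
    n = pop.size
    r6 = rng.random(n)
    r = rng.random(n)
    bounds_range = float(np.mean(space.range))
    h = hunger_increment(pop.fitness, pop.best_fitness, pop.worst_fitness,
                         bounds_range, params.lh, r6, r)
    is_best = pop.fitness == pop.best_fitness
    pop.hunger = np.where(is_best, 0.0, pop.hunger + h)


def optimize(objective, params: HGSParams | None = None, *,
             fuzzy=None, reduction=None,
             rng: RandomStream | int | None = None,
             record_mutations: bool = False) -> RunResult:
    """Run (m)HGS on ``objective`` until the evaluation budget is spent.

    Parameters
    ----------
    objective
        An :class:`mhgs.benchmarks.ObjectiveFunction` (or any object with a
        ``space`` attribute and an ``evaluate_batch(X) -> values`` method).
        Minimization is assumed.
    params : HGSParams
        Engine settings; defaults to ``HGSParams()``.
    fuzzy : FuzzyMutationParams or None
        Centroid-based fuzzy mutation settings; ``None`` disables the
        operator (plain-HGS ablation).
    reduction : ReductionPolicy or None
        Linear population-size reduction; ``None`` keeps N fixed.
    rng : RandomStream or int
        Randomness source; an int is treated as a seed.

    Returns
    -------
    RunResult
        Best solution found, a monotone non-increasing (fe, best_fitness)
        trace with one point per generation, and the run configuration.
    """
    params = params or HGSParams()
    if rng is None:
        rng = RandomStream(0)
    elif isinstance(rng, (int, np.integer)):
        rng = RandomStream(int(rng))
    space: SearchSpace = objective.space

    search = rng.child("search")
    mutation_rng = rng.child("mutation")
    pop = initialize_population(space, params, rng.child("init"))

    from .fuzzy import propose_mutations  # local import; avoids cycle

    t0 = time.perf_counter()
    trace: list[tuple[int, float]] = []
    mutation_log: list[dict] = []
    while pop.fe < params.max_fe:
        n_eval = min(pop.size, params.max_fe - pop.fe)
        values = np.asarray(
            objective.evaluate_batch(pop.positions[:n_eval]), dtype=float)
        if not np.all(np.isfinite(values)):
            bad = int(np.argmax(~np.isfinite(values)))
            raise RuntimeError(
                f"objective returned a non-finite value ({values[bad]}) at "
                f"position {pop.positions[bad]!r} after {pop.fe} evaluations")
        pop.fitness[:n_eval] = values
        pop.fe += n_eval
        evaluated = pop.fitness[:n_eval]

        gen_best = int(np.argmin(evaluated))
        if evaluated[gen_best] < pop.best_fitness:
            pop.best_fitness = float(evaluated[gen_best])
            pop.best_position = pop.positions[gen_best].copy()
            pop.unchanged = 0
        else:
            pop.unchanged += 1
        pop.worst_fitness = float(np.max(evaluated))

        # Fuzzy mutation phase: draw candidates, evaluate the fired ones,
        # and keep each candidate only where it improves on the agent's
        # current solution (greedy comparison of new vs previous).
        if fuzzy is not None and pop.fe < params.max_fe:
            candidates, decisions = propose_mutations(
                pop, space, fuzzy, count=pop.fe, iter_total=params.max_fe,
                rng=mutation_rng)
            fired = [i for i, d in enumerate(decisions) if d.fired]
            fired = fired[: params.max_fe - pop.fe]
            if fired:
                cand_vals = np.asarray(
                    objective.evaluate_batch(candidates[fired]), dtype=float)
                if not np.all(np.isfinite(cand_vals)):
                    raise RuntimeError(
                        "objective returned a non-finite value during the "
                        f"mutation phase after {pop.fe} evaluations")
                pop.fe += len(fired)
                better = cand_vals < pop.fitness[fired]
                accept = np.asarray(fired)[better]
                pop.positions[accept] = candidates[accept]
                pop.fitness[accept] = cand_vals[better]
                if better.any():
                    j = int(np.argmin(cand_vals))
                    if cand_vals[j] < pop.best_fitness:
                        pop.best_fitness = float(cand_vals[j])
                        pop.best_position = candidates[fired[j]].copy()
                        pop.unchanged = 0
            if record_mutations:
                for i, d in enumerate(decisions):
                    mutation_log.append({
                        "fe": pop.fe, "agent_id": i, "P_d": d.p_distance,
                        "P_c": d.p_history, "P_l": d.p_mutation,
                        "fired": d.fired,
                    })

        trace.append((pop.fe, pop.best_fitness))
        if pop.fe >= params.max_fe:
            break

        _update_hunger_inplace(pop, space, params, search)

        n, dim = pop.size, space.dim
        e = variation_control(pop.fitness, pop.best_fitness)[:, None]
        a = shrink_factor(pop.fe, params.max_fe)
        r3 = search.random((n, 1))
        r4, r5 = search.random((n, dim)), search.random((n, dim))
        w1, w2 = hunger_weights(pop.hunger[:, None], pop.hunger_sum, n,
                                params.l, r3, r4, r5)
        r1 = search.random((n, 1))          # whole-agent branch gate
        r2 = search.random((n, dim))        # per-coordinate approach/depart
        z = search.normal(size=(n, 1))      # single scalar per agent
        r_step = 2.0 * a * search.random((n, 1)) - a
        proposed = position_update(pop.positions, pop.best_position,
                                   w1, w2, r_step, e, params.l, r1, r2, z)
        pop.positions = clamp_to_bounds(proposed, space)

        if reduction is not None:
            from .reduction import next_population_size, shrink_population
            target = next_population_size(pop.fe, reduction)
            if target < pop.size:
                shrink_population(pop, target)

    config = {
        "n_agents": params.n_agents, "max_fe": params.max_fe,
        "l": params.l, "lh": params.lh,
        "fuzzy": fuzzy is not None, "reduction": reduction is not None,
        "objective": getattr(objective, "name", repr(objective)),
    }
    return RunResult(
        best_fitness=pop.best_fitness,
        best_position=pop.best_position,
        trace=trace,
        seed=rng.seed,
        n_evaluations=pop.fe,
        config=config,
        cpu_seconds=time.perf_counter() - t0,
        mutation_log=mutation_log,
    )
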