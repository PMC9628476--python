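"""Canonical experiment protocols.

These runners pin the study conditions used throughout the package's
documentation and validation: the benchmark protocol (30 independent runs,
30 agents, 45 000 evaluations, 10-D), the sphere convergence check, the
paired-seed comparison against pure random search, and the synthetic
feature-selection recovery experiment. They are shared by the test suite
and ``scripts/acceptance.py`` so both execute the same computation.
"""

from __future__ import annotations

import numpy as np

from .benchmarks import make_benchmark
from .core import HGSParams, RunResult, optimize
from .features import FSFitnessParams, run_feature_selection
from .fuzzy import FuzzyMutationParams
from .rng import RandomStream
from .stats import summarize_runs
from .synth import SyntheticSpec, generate_dataset, recovery_score

__all__ = ["derive_seeds", "benchmark_protocol", "sphere_convergence",
           "random_search", "random_search_dominance", "fs_recovery_protocol"]


def derive_seeds(base_seed: int, n: int, salt: int = 0) -> list[int]:
    """n distinct per-run seeds from one base seed, all below 2^31."""
    return [(base_seed * 10007 + salt * 104729 + i) % (2**31 - 1)
            for i in range(n)]


def benchmark_protocol(fid: str, *, dim: int = 10, runs: int = 30,
                       n_agents: int = 30, max_fe: int = 45000,
                       base_seed: int = 1,
                       fuzzy: FuzzyMutationParams | None = None,
                       reduction=None, use_fuzzy: bool = True) -> dict:
    """The benchmark-table protocol: independent seeded mHGS runs.

    Each run gets a freshly seeded function instance (its own
    shift/rotation) and engine stream. With ``n_agents`` equal to the
    reduction floor the population size is constant, so only the fuzzy
    mutation distinguishes mHGS from plain HGS here.
    """
    if use_fuzzy and fuzzy is None:
        fuzzy = FuzzyMutationParams()
    params = HGSParams(n_agents=n_agents, max_fe=max_fe)
    results: list[RunResult] = []
    for i, seed in enumerate(derive_seeds(base_seed, runs)):
        objective = make_benchmark(fid, dim, rng=RandomStream(seed).child("instance"))
        res = optimize(objective, params, fuzzy=fuzzy, reduction=reduction,
                       rng=seed)
        results.append(res)
    finals = [r.best_fitness for r in results]
    return {"fid": fid, "results": results, "finals": finals,
            "summary": summarize_runs(finals, direction="minimize")}


def sphere_convergence(*, dim: int = 2, max_fe: int = 5000,
                       n_seeds: int = 20, base_seed: int = 1) -> list[float]:
    """Best fitness on the plain sphere for each of ``n_seeds`` seeds."""
    params = HGSParams(n_agents=30, max_fe=max_fe)
    out = []
    for seed in derive_seeds(base_seed, n_seeds, salt=1):
        objective = make_benchmark("sphere", dim)
        res = optimize(objective, params, fuzzy=FuzzyMutationParams(),
                       rng=seed)
        out.append(res.best_fitness)
    return out


def random_search(objective, max_fe: int, rng: RandomStream) -> float:
    """Independent test oracle: best value of uniform random sampling."""
    space = objective.space
    best = np.inf
    batch = 1000
    spent = 0
    while spent < max_fe:
        m = min(batch, max_fe - spent)
        X = space.lower + rng.random((m, space.dim)) * space.range
        best = min(best, float(np.min(objective.evaluate_batch(X))))
        spent += m
    return best


def random_search_dominance(*, dim: int = 10, max_fe: int = 10000,
                            pairs: int = 20, base_seed: int = 1) -> dict:
    """Paired-seed comparison of mHGS vs pure random search on the sphere."""
    params = HGSParams(n_agents=30, max_fe=max_fe)
    wins = 0
    for seed in derive_seeds(base_seed, pairs, salt=2):
        objective = make_benchmark("sphere", dim)
        res = optimize(objective, params, fuzzy=FuzzyMutationParams(),
                       rng=seed)
        rs = random_search(objective, max_fe,
                           RandomStream(seed).child("random-search"))
        if res.best_fitness <= rs:
            wins += 1
    return {"wins": wins, "pairs": pairs, "rate": wins / pairs}


def fs_recovery_protocol(*, runs: int = 10, max_fe: int = 5000,
                         base_seed: int = 1,
                         spec: SyntheticSpec | None = None) -> dict:
    """Synthetic feature-selection recovery experiment.

    Generates a descriptor table with known informative features (defaults:
    300 samples × 50 features, 5 informative, class separation 3, 5% label
    noise), runs the wrapper protocol, and scores Jaccard recovery of the
    true informative subset plus hold-out accuracy against the all-features
    baseline.
    """
    spec = spec or SyntheticSpec(seed=base_seed % (2**31 - 1))
    data = generate_dataset(spec)
    report = run_feature_selection(
        data,
        HGSParams(n_agents=30, max_fe=max_fe),
        fuzzy=FuzzyMutationParams(),
        fs=FSFitnessParams(),
        runs=runs,
        seeds=derive_seeds(base_seed, runs, salt=3),
    )
    jaccard = [recovery_score(r["mask"], data.informative_mask)
               for r in report["runs"]]
    report["jaccard"] = jaccard
    report["jaccard_mean"] = float(np.mean(jaccard))
    report["accuracy_mean"] = float(np.mean(
        [r["accuracy"] for r in report["runs"]]))
    report["baseline_accuracy_mean"] = float(np.mean(
        [r["baseline_accuracy"] for r in report["runs"]]))
    return report
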