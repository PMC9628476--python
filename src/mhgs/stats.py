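"""Run-level statistics, Friedman mean ranks, and trace export.

Summaries follow the convention of metaheuristic benchmarking tables:
mean, sample standard deviation (denominator M-1), and direction-aware
best/worst over M independent runs. The Friedman mean rank is computed per
(problem, run) cell with mid-ranks on ties, then averaged per algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["RunSummary", "RankTable", "summarize_runs",
           "friedman_mean_rank", "export_traces", "write_summary_csv"]


@dataclass
class RunSummary:
    mean: float
    std: float
    best: float
    worst: float
    n_runs: int
    direction: str

    def as_dict(self) -> dict:
        return {"mean": self.mean, "std": self.std, "best": self.best,
                "worst": self.worst, "n_runs": self.n_runs,
                "direction": self.direction}


def summarize_runs(values, direction: str = "minimize") -> RunSummary:
    """Mean / sample std / best / worst of per-run outcomes.

    ``direction`` decides which extremum is "best": the minimum for
    minimized objectives (benchmark fitness), the maximum for maximized
    ones (classification accuracy).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty list of runs")
    if direction not in ("minimize", "maximize"):
        raise ValueError("direction must be 'minimize' or 'maximize'")
    if values.size == 1:
        warnings.warn("std of a single run reported as 0", stacklevel=2)
        std = 0.0
    else:
        std = float(np.std(values, ddof=1))
    lo, hi = float(np.min(values)), float(np.max(values))
    best, worst = (lo, hi) if direction == "minimize" else (hi, lo)
    return RunSummary(mean=float(np.mean(values)), std=std, best=best,
                      worst=worst, n_runs=int(values.size),
                      direction=direction)


@dataclass
class RankTable:
    """Per-cell ranks (algorithms × problems × runs) and mean ranks."""

    algorithms: list[str]
    ranks: np.ndarray
    mean_ranks: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.algorithms, self.mean_ranks.tolist()))


def friedman_mean_rank(values, algorithms=None,
                       direction: str = "minimize") -> RankTable:
    """Friedman-style mean ranks over (problem, run) cells.

    ``values`` has shape (n_algorithms, n_problems, n_runs); within each
    (problem, run) cell algorithms are ranked 1..k (1 = best under
    ``direction``, ties mid-ranked) and each algorithm's ranks are averaged
    over all cells. Lower mean rank is better.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    if values.ndim != 3:
        raise ValueError("values must have shape (algorithms, problems, runs)")
    if np.isnan(values).any():
        raise ValueError("rank table has missing cells")
    k = values.shape[0]
    if algorithms is None:
        algorithms = [f"alg{i}" for i in range(k)]
    signed = values if direction == "minimize" else -values
    ranks = rankdata(signed, method="average", axis=0)
    mean_ranks = ranks.reshape(k, -1).mean(axis=1)
    return RankTable(list(algorithms), ranks, mean_ranks)


def export_traces(results, outdir) -> tuple[str, str]:
    """Write convergence and boxplot CSVs for a list of RunResults.

    ``convergence.csv`` holds (run, fe, best_fitness) for every recorded
    trace point; ``boxplot.csv`` holds one final best fitness per run. The
    monotone non-increasing trace invariant is re-checked at export time.
    """
    import os
    results = list(results)
    if not results:
        raise ValueError("no results to export")
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, res in enumerate(results):
        last = np.inf
        for fe, bf in res.trace:
            if bf > last + 1e-15:
                raise ValueError(
                    f"run {i}: best-fitness trace increases at fe={fe}")
            last = bf
            rows.append((i, fe, bf))
    conv = os.path.join(outdir, "convergence.csv")
    pd.DataFrame(rows, columns=["run", "fe", "best_fitness"]).to_csv(
        conv, index=False)
    box = os.path.join(outdir, "boxplot.csv")
    pd.DataFrame(
        {"run": range(len(results)),
         "final_fitness": [r.best_fitness for r in results]}
    ).to_csv(box, index=False)
    return conv, box


def write_summary_csv(path, rows) -> None:
    """Write a benchmark-table summary CSV.

    ``rows`` is an iterable of dicts with keys like
    (function, algorithm, mean, std, best, worst, n_runs).
    """
    pd.DataFrame(list(rows)).to_csv(path, index=False)
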