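"""Wrapper feature selection with a classifier in the loop.

Continuous agent positions on [0, 1]^d are binarized into feature masks; a
mask's fitness combines the hold-out error rate of a classifier trained on
the selected descriptors with a penalty on the subset size:

    fobj = alpha·R + (1 - alpha)·|selected| / d        (minimized)

with alpha = 0.99 by default, so accuracy dominates and the size term breaks
ties toward smaller subsets. A "literal" mode of the printed objective
(alpha + beta·|R|/|C| - G with beta = alpha, flagged against a threshold T)
is retained for fidelity experiments.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import stats as _stats
from .core import HGSParams, optimize
from .rng import RandomStream
from .space import SearchSpace
from .benchmarks import ObjectiveFunction

__all__ = [
    "DescriptorDataset",
    "FeatureMask",
    "FSFitnessParams",
    "SVMClassifier",
    "binarize_position",
    "wrapper_fitness",
    "split_dataset",
    "run_feature_selection",
]


@dataclass
class DescriptorDataset:
    """A numeric sample × feature table with class labels.

    Emulates QSAR-style descriptor matrices (rows = compounds, columns =
    molecular descriptors, plus one categorical label column).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    informative_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, d = self.X.shape
        if n < 10:
            raise ValueError("need at least 10 samples")
        if d < 2:
            raise ValueError("need at least 2 features")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if len(self.y) != n:
            raise ValueError("label vector length mismatch")
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        if np.any(counts < 2):
            bad = classes[np.argmin(counts)]
            raise ValueError(f"class {bad!r} has fewer than 2 samples")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_csv(cls, path, label_col: str | None = None) -> "DescriptorDataset":
        """Read a header CSV; ``label_col`` defaults to the last column."""
        df = pd.read_csv(path)
        if label_col is None:
            label_col = df.columns[-1]
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not in CSV header")
        y = df[label_col].to_numpy()
        feats = df.drop(columns=[label_col])
        return cls(feats.to_numpy(dtype=float), y, list(feats.columns))

    def to_csv(self, path, label_col: str = "label") -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_col] = self.y
        df.to_csv(path, index=False)


@dataclass
class FeatureMask:
    """Binary feature-inclusion vector; never empty."""

    selected: np.ndarray

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.ndim != 1:
            raise ValueError("mask must be a 1-D boolean vector")
        if not self.selected.any():
            raise ValueError("mask must select at least one feature")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def __len__(self) -> int:
        return self.selected.size


@dataclass
class FSFitnessParams:
    """Wrapper-fitness settings (canonical or literal objective)."""

    alpha_w: float = 0.99
    threshold: float = 0.5
    mode: str = "canonical"
    T: float = 0.0
    G: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.alpha_w <= 1.0):
            raise ValueError("alpha_w must be in [0, 1]")
        if self.mode not in ("canonical", "literal"):
            raise ValueError("mode must be 'canonical' or 'literal'")


class SVMClassifier:
    """Default classifier contract: RBF-kernel SVM, C = 1, gamma = 1/d_sel.

    Features are z-scored on the training fold only (leakage-safe). The
    kernel internals are delegated to scikit-learn; this class only pins the
    deterministic configuration the wrapper relies on.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self._model = None
        self._scaler = None

    def fit(self, X, y):
        self._scaler = StandardScaler()
        Xs = self._scaler.fit_transform(X)
        gamma = 1.0 / X.shape[1]
        self._model = SVC(C=self.C, kernel="rbf", gamma=gamma)
        self._model.fit(Xs, y)
        return self

    def predict(self, X):
        return self._model.predict(self._scaler.transform(X))

    def error_rate(self, X, y) -> float:
        return float(np.mean(self.predict(X) != y))

    def clone(self) -> "SVMClassifier":
        return SVMClassifier(C=self.C)


def binarize_position(position, params: FSFitnessParams | None = None) -> FeatureMask:
    """Threshold a [0, 1]^d position into a mask (argmax fallback).

    Feature j is selected iff position_j >= threshold; if nothing passes,
    the single largest coordinate is selected so the classifier always
    receives at least one feature.
    """
    params = params or FSFitnessParams()
    position = np.asarray(position, dtype=float)
    mask = position >= params.threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return FeatureMask(mask)


@dataclass
class Split:
    """A prepared train/test split (row indices into the dataset)."""

    train_idx: np.ndarray
    test_idx: np.ndarray


def split_dataset(data: DescriptorDataset, rng: RandomStream,
                  test_fraction: float = 0.1) -> Split:
    """Stratified hold-out split, 90% train / 10% test by default.

    The test size is round-half-up of ``test_fraction·n`` (e.g. 7 of 68);
    per-class proportions are preserved within ±1 sample.
    """
    classes, counts = np.unique(data.y, return_counts=True)
    if np.any(counts < 2):
        bad = classes[np.argmin(counts)]
        raise ValueError(f"class {bad!r} has fewer than 2 samples")
    n_test = int(np.floor(test_fraction * data.n_samples + 0.5))
    n_test = max(n_test, len(classes))  # stratification needs one per class
    seed = int(rng.integers(0, 2**31 - 1))
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=n_test,
                                      random_state=seed)
    train_idx, test_idx = next(splitter.split(data.X, data.y))
    return Split(train_idx=train_idx, test_idx=test_idx)


def wrapper_fitness(mask: FeatureMask, data: DescriptorDataset,
                    clf, params: FSFitnessParams, split: Split):
    """Score one mask: train on the selected columns, measure hold-out error.

    Canonical mode returns the minimized objective
    ``alpha·R + (1-alpha)·|sel|/d``. Literal mode returns
    ``(fobj, exceeds_T)`` with ``fobj = alpha + beta·|R|/|C| - G`` and
    ``beta = alpha`` (G defaults to 0; both G and T are free parameters of
    the printed form).
    """
    cols = np.flatnonzero(mask.selected)
    Xtr = data.X[np.ix_(split.train_idx, cols)]
    Xte = data.X[np.ix_(split.test_idx, cols)]
    try:
        model = clf.clone().fit(Xtr, data.y[split.train_idx])
        error = model.error_rate(Xte, data.y[split.test_idx])
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"classifier failed on mask with {mask.n_selected} features: {exc}"
        ) from exc
    d = data.n_features
    if params.mode == "canonical":
        return params.alpha_w * error + (1.0 - params.alpha_w) * mask.n_selected / d
    beta = params.alpha_w
    fobj = params.alpha_w + beta * abs(error) / d - params.G
    return fobj, fobj > params.T


def _fs_objective(data: DescriptorDataset, clf, params: FSFitnessParams,
                  split: Split) -> ObjectiveFunction:
    space = SearchSpace(data.n_features, 0.0, 1.0)

    def fn(X):
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            mask = binarize_position(row, params)
            out[i] = wrapper_fitness(mask, data, clf, params, split)
        return out

    return ObjectiveFunction(name="wrapper-fs", space=space, fn=fn)


def run_feature_selection(data: DescriptorDataset,
                          hgs: HGSParams | None = None, *,
                          fuzzy=None, reduction=None,
                          fs: FSFitnessParams | None = None,
                          clf=None, runs: int = 30,
                          seeds: Sequence[int] | None = None) -> dict:
    """Full mHGS-FS protocol: independent seeded runs, aggregated report.

    Each run draws its own stratified 90/10 split, optimizes a mask over
    [0, 1]^d under the wrapper fitness, and reports the best mask's hold-out
    accuracy, size, fitness and CPU time, plus the all-features baseline
    accuracy on the same split. Aggregates (mean/std/best/worst) follow the
    maximize direction for accuracy and minimize for fitness.
    """
    hgs = hgs or HGSParams()
    fs = fs or FSFitnessParams()
    if fs.mode != "canonical":
        raise ValueError("run_feature_selection requires the canonical objective")
    clf = clf or SVMClassifier()
    if seeds is None:
        seeds = list(range(runs))
    if len(seeds) != runs:
        raise ValueError("need exactly one seed per run")

    per_run = []
    frequency = np.zeros(data.n_features)
    for seed in seeds:
        rng = RandomStream(int(seed))
        split = split_dataset(data, rng.child("split"))
        objective = _fs_objective(data, clf, fs, split)
        t0 = time.perf_counter()
        result = optimize(objective, hgs, fuzzy=fuzzy, reduction=reduction,
                          rng=rng)
        elapsed = time.perf_counter() - t0
        mask = binarize_position(result.best_position, fs)
        cols = np.flatnonzero(mask.selected)
        model = clf.clone().fit(data.X[np.ix_(split.train_idx, cols)],
                                data.y[split.train_idx])
        accuracy = 1.0 - model.error_rate(data.X[np.ix_(split.test_idx, cols)],
                                          data.y[split.test_idx])
        baseline = clf.clone().fit(data.X[split.train_idx],
                                   data.y[split.train_idx])
        baseline_acc = 1.0 - baseline.error_rate(data.X[split.test_idx],
                                                 data.y[split.test_idx])
        frequency += mask.selected
        per_run.append({
            "seed": int(seed),
            "accuracy": accuracy,
            "baseline_accuracy": baseline_acc,
            "n_selected": mask.n_selected,
            "fitness": result.best_fitness,
            "cpu_seconds": elapsed,
            "mask": mask.selected.copy(),
        })

    acc = [r["accuracy"] for r in per_run]
    fit = [r["fitness"] for r in per_run]
    nsel = [r["n_selected"] for r in per_run]
    report = {
        "runs": per_run,
        "aggregate": {
            "accuracy": _stats.summarize_runs(acc, direction="maximize"),
            "fitness": _stats.summarize_runs(fit, direction="minimize"),
            "n_selected": _stats.summarize_runs(nsel, direction="minimize"),
            "baseline_accuracy_mean": float(np.mean(
                [r["baseline_accuracy"] for r in per_run])),
        },
        "selection_frequency": frequency / runs,
        "feature_names": list(data.feature_names),
    }
    return report
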