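"""Seeded generator of descriptor-like classification datasets.

Emulates QSAR molecular-descriptor tables (compounds × descriptors with a
binary activity label) with a *known* informative-feature subset, so that
feature-selection behaviour is testable end to end without any download or
chemistry pipeline: an informative block of class-conditional Gaussians,
a redundant block of linear mixtures of the informative features, and an
independent Gaussian noise block. Ground truth is attached as a mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .features import DescriptorDataset, FeatureMask
from .rng import RandomStream

__all__ = ["SyntheticSpec", "generate_dataset", "recovery_score"]


@dataclass
class SyntheticSpec:
    """Shape and signal parameters of a synthetic descriptor table.

    Each informative feature is class-conditionally Gaussian with unit
    variance and class means ``class_sep`` apart (random sign per feature);
    redundant features are seeded linear mixtures of informative ones plus
    small noise; the remaining features are pure standard-Gaussian noise
    independent of the labels. ``flip_y`` is the label-noise fraction.
    """

    n_samples: int = 300
    n_features: int = 50
    n_informative: int = 5
    n_redundant: int = 0
    n_noise: Optional[int] = None
    class_sep: float = 3.0
    flip_y: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_noise is None:
            self.n_noise = self.n_features - self.n_informative - self.n_redundant
        if self.n_informative < 1:
            raise ValueError("need at least 1 informative feature")
        if self.n_noise < 0 or (self.n_informative + self.n_redundant
                                + self.n_noise != self.n_features):
            raise ValueError(
                "n_informative + n_redundant + n_noise must equal n_features")
        if self.class_sep < 0:
            raise ValueError("class_sep must be >= 0")
        if not (0.0 <= self.flip_y < 0.5):
            raise ValueError("flip_y must be in [0, 0.5)")


def generate_dataset(spec: SyntheticSpec) -> DescriptorDataset:
    """Draw a dataset from ``spec``; same spec + seed is bit-identical."""
    rng = RandomStream(spec.seed)
    n, k = spec.n_samples, spec.n_informative

    # Balanced labels, then shuffled.
    y = np.zeros(n, dtype=int)
    y[n // 2:] = 1
    y = y[rng.permutation(n)]

    # Informative block: each feature's class-conditional means differ by
    # class_sep (offset ±class_sep/2, random sign per feature), unit
    # variance — the same per-feature separation convention as sklearn's
    # make_classification.
    signs = rng.sign(k)
    offset = signs * spec.class_sep / 2.0
    X_inf = rng.normal(size=(n, k)) + np.where(y[:, None] == 1, offset, -offset)

    blocks = [X_inf]
    if spec.n_redundant > 0:
        coeff = rng.normal(size=(spec.n_redundant, k))
        coeff /= np.linalg.norm(coeff, axis=1, keepdims=True)
        X_red = X_inf @ coeff.T + 0.05 * rng.normal(size=(n, spec.n_redundant))
        blocks.append(X_red)
    if spec.n_noise > 0:
        blocks.append(rng.normal(size=(n, spec.n_noise)))
    X = np.hstack(blocks)

    if spec.flip_y > 0:
        flip = rng.random(n) < spec.flip_y
        y = np.where(flip, 1 - y, y)

    names = ([f"inf_{j}" for j in range(k)]
             + [f"red_{j}" for j in range(spec.n_redundant)]
             + [f"noise_{j}" for j in range(spec.n_noise)])
    truth = np.zeros(spec.n_features, dtype=bool)
    truth[:k] = True
    return DescriptorDataset(X=X, y=y, feature_names=names,
                             informative_mask=truth)


def recovery_score(mask, truth) -> float:
    """Jaccard index |mask ∩ truth| / |mask ∪ truth| of two feature masks."""
    a = mask.selected if isinstance(mask, FeatureMask) else np.asarray(mask, bool)
    b = truth.selected if isinstance(truth, FeatureMask) else np.asarray(truth, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
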