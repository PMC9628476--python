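"""Search-space description and boundary handling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SearchSpace", "clamp_to_bounds"]


@dataclass(frozen=True)
class SearchSpace:
    """A box-constrained continuous search space.

    Attributes
    ----------
    dim : int
        Number of decision variables (>= 1).
    lower, upper : ndarray of shape (dim,)
        Per-dimension bounds, ``lower <= upper`` element-wise. Scalars are
        broadcast to every dimension.
    """

    dim: int
    lower: np.ndarray = field(repr=False)
    upper: np.ndarray = field(repr=False)

    def __init__(self, dim: int, lower, upper):
        if dim < 1:
            raise ValueError(f"dim must be >= 1, got {dim}")
        lo = np.broadcast_to(np.asarray(lower, dtype=float), (dim,)).copy()
        hi = np.broadcast_to(np.asarray(upper, dtype=float), (dim,)).copy()
        if np.any(lo > hi):
            bad = int(np.argmax(lo > hi))
            raise ValueError(
                f"invalid space: lower bound exceeds upper bound at dimension "
                f"{bad} ({lo[bad]} > {hi[bad]})"
            )
        object.__setattr__(self, "dim", int(dim))
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def range(self) -> np.ndarray:
        """Per-dimension width ``upper - lower``."""
        return self.upper - self.lower

    @property
    def diagonal(self) -> float:
        """Euclidean length of the box diagonal."""
        return float(np.linalg.norm(self.range))

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


def clamp_to_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Project ``position`` (a vector or an (n, dim) batch) onto the box."""
    return np.clip(np.asarray(position, dtype=float), space.lower, space.upper)
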