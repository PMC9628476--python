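"""Deterministic random streams.

Every stochastic component of the package draws from a :class:`RandomStream`.
Streams are derived from a single integer seed through numpy's
``SeedSequence`` machinery; named child streams are independent of each other
and of their parent, so optional components (e.g. the fuzzy mutation) can
consume randomness without perturbing the main search trajectory.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["RandomStream"]


class RandomStream:
    """A seeded numpy generator with reproducible named sub-streams.

    Parameters
    ----------
    seed : int
        Root seed. Identical seeds yield bit-identical draw sequences.
    """

    def __init__(self, seed: int, _seq: np.random.SeedSequence | None = None):
        self.seed = int(seed)
        self._seq = np.random.SeedSequence(self.seed) if _seq is None else _seq
        self.generator = np.random.default_rng(self._seq)

    def child(self, name: str) -> "RandomStream":
        """Return an independent stream keyed by ``name``.

        The same (seed, name) pair always yields the same stream, regardless
        of the order in which children are created.
        """
        key = zlib.crc32(name.encode("utf-8"))
        seq = np.random.SeedSequence(
            entropy=self._seq.entropy,
            spawn_key=tuple(self._seq.spawn_key) + (key,),
        )
        return RandomStream(self.seed, _seq=seq)

    # Convenience draw helpers -------------------------------------------------

    def uniform(self, low=0.0, high=1.0, size=None):
        return self.generator.uniform(low, high, size)

    def random(self, size=None):
        return self.generator.random(size)

    def normal(self, loc=0.0, scale=1.0, size=None):
        return self.generator.normal(loc, scale, size)

    def integers(self, low, high=None, size=None):
        return self.generator.integers(low, high, size)

    def sign(self, size=None):
        """Random ±1 with equal probability."""
        return self.generator.choice(np.array([-1.0, 1.0]), size=size)

    def permutation(self, n: int):
        return self.generator.permutation(n)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RandomStream(seed={self.seed})"
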