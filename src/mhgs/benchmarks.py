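"""CEC'20-style continuous benchmark functions.

Ten bound-constrained test functions on [-100, 100]^D following the CEC'20
single-objective suite structure: one unimodal (shifted/rotated bent cigar),
three multimodal (Schwefel, Lunacek bi-Rastrigin, expanded
Rosenbrock-plus-Griewank), three hybrids and three compositions, each with
an additive bias that is the function value at the constructed optimum.

By default every instance draws its own shift vector (uniform in the inner
80% of the range, so the optimum never touches the boundary) and rotation
matrix (Haar-orthogonal) from a seeded stream; this preserves each
function's optimum *value* exactly. Official whitespace-text data files can
be supplied instead, giving the same function contract.

All base functions are vectorized over an (n, D) batch of positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .rng import RandomStream
from .space import SearchSpace

__all__ = [
    "ObjectiveFunction",
    "EvaluationBudget",
    "BudgetExhausted",
    "make_rotation",
    "make_benchmark",
    "evaluate_with_budget",
    "load_matrix",
    "export_landscape_grid",
    "BASE_FUNCTIONS",
    "CEC20_BIAS",
    "CEC20_IDS",
]


# ---------------------------------------------------------------------------
# Base functions (inputs already shifted/rotated/scaled to native domain)
# ---------------------------------------------------------------------------

def sphere(z):
    return np.sum(z * z, axis=-1)


def bent_cigar(z):
    return z[..., 0] ** 2 + 1e6 * np.sum(z[..., 1:] ** 2, axis=-1)


def elliptic(z):
    d = z.shape[-1]
    if d == 1:
        return z[..., 0] ** 2
    cond = np.power(1e6, np.arange(d) / (d - 1))
    return np.sum(cond * z * z, axis=-1)


def discus(z):
    return 1e6 * z[..., 0] ** 2 + np.sum(z[..., 1:] ** 2, axis=-1)


def rastrigin(z):
    return np.sum(z * z - 10.0 * np.cos(2.0 * np.pi * z) + 10.0, axis=-1)


def ackley(z):
    d = z.shape[-1]
    s1 = np.sqrt(np.sum(z * z, axis=-1) / d)
    s2 = np.sum(np.cos(2.0 * np.pi * z), axis=-1) / d
    return -20.0 * np.exp(-0.2 * s1) - np.exp(s2) + 20.0 + np.e


def griewank(z):
    d = z.shape[-1]
    idx = np.sqrt(np.arange(1, d + 1))
    return (np.sum(z * z, axis=-1) / 4000.0
            - np.prod(np.cos(z / idx), axis=-1) + 1.0)


def rosenbrock(z):
    """Native Rosenbrock with the CEC +1 shift: minimum 0 at z = 0."""
    y = z + 1.0
    return np.sum(100.0 * (y[..., :-1] ** 2 - y[..., 1:]) ** 2
                  + (y[..., :-1] - 1.0) ** 2, axis=-1)


_SCHWEFEL_X0 = 420.9687462275036
_SCHWEFEL_C = _SCHWEFEL_X0 * np.sin(np.sqrt(_SCHWEFEL_X0))  # 418.98288727...


def schwefel(z):
    """Modified Schwefel with out-of-range penalty; minimum 0 at z = 0."""
    d = z.shape[-1]
    w = z + _SCHWEFEL_X0
    aw = np.abs(w)
    g_in = w * np.sin(np.sqrt(aw))
    wm = np.mod(aw, 500.0)
    g_hi = ((500.0 - wm) * np.sin(np.sqrt(np.abs(500.0 - wm)))
            - (w - 500.0) ** 2 / (10000.0 * d))
    g_lo = ((wm - 500.0) * np.sin(np.sqrt(np.abs(wm - 500.0)))
            - (w + 500.0) ** 2 / (10000.0 * d))
    g = np.where(aw <= 500.0, g_in, np.where(w > 500.0, g_hi, g_lo))
    return _SCHWEFEL_C * d - np.sum(g, axis=-1)


def schaffer_f6_expanded(z):
    x, y = z, np.roll(z, -1, axis=-1)
    ss = x * x + y * y
    g = 0.5 + (np.sin(np.sqrt(ss)) ** 2 - 0.5) / (1.0 + 0.001 * ss) ** 2
    return np.sum(g, axis=-1)


def hgbat(z):
    d = z.shape[-1]
    y = z - 1.0
    s2 = np.sum(y * y, axis=-1)
    s1 = np.sum(y, axis=-1)
    return (np.sqrt(np.abs(s2 ** 2 - s1 ** 2))
            + (0.5 * s2 + s1) / d + 0.5)


def happycat(z):
    d = z.shape[-1]
    y = z - 1.0
    s2 = np.sum(y * y, axis=-1)
    s1 = np.sum(y, axis=-1)
    return (np.abs(s2 - d) ** 0.25 + (0.5 * s2 + s1) / d + 0.5)


def grie_rosen(z):
    """Expanded Griewank-of-Rosenbrock over cyclic coordinate pairs."""
    y = z + 1.0
    x1, x2 = y, np.roll(y, -1, axis=-1)
    t = 100.0 * (x1 ** 2 - x2) ** 2 + (x1 - 1.0) ** 2
    return np.sum(t * t / 4000.0 - np.cos(t) + 1.0, axis=-1)


def lunacek_bi_rastrigin(z):
    """Two-funnel Rastrigin hybrid; minimum 0 at z = 0 (native scale)."""
    d = z.shape[-1]
    mu0 = 2.5
    s = 1.0 - 1.0 / (2.0 * np.sqrt(d + 20.0) - 8.2)
    mu1 = -np.sqrt((mu0 ** 2 - 1.0) / s)
    xhat = z + mu0
    t1 = np.sum((xhat - mu0) ** 2, axis=-1)
    t2 = d + s * np.sum((xhat - mu1) ** 2, axis=-1)
    cosz = np.sum(np.cos(2.0 * np.pi * (xhat - mu0)), axis=-1)
    return np.minimum(t1, t2) + 10.0 * (d - cosz)


BASE_FUNCTIONS: dict[str, Callable] = {
    "sphere": sphere,
    "bent_cigar": bent_cigar,
    "elliptic": elliptic,
    "discus": discus,
    "rastrigin": rastrigin,
    "ackley": ackley,
    "griewank": griewank,
    "rosenbrock": rosenbrock,
    "schwefel": schwefel,
    "schaffer_f6_expanded": schaffer_f6_expanded,
    "hgbat": hgbat,
    "happycat": happycat,
    "grie_rosen": grie_rosen,
    "lunacek_bi_rastrigin": lunacek_bi_rastrigin,
}

# Native bounds for plain (unshifted) base functions.
_PLAIN_BOUNDS = {
    "sphere": 100.0, "bent_cigar": 100.0, "elliptic": 100.0, "discus": 100.0,
    "rastrigin": 5.12, "ackley": 32.768, "griewank": 600.0,
    "rosenbrock": 30.0, "schwefel": 500.0, "schaffer_f6_expanded": 100.0,
    "hgbat": 100.0, "happycat": 100.0, "grie_rosen": 5.0,
    "lunacek_bi_rastrigin": 5.12,
}


# ---------------------------------------------------------------------------
# Objective-function contract and evaluation budget
# ---------------------------------------------------------------------------

@dataclass
class ObjectiveFunction:
    """A named, bounded, batch-evaluable objective (minimization).

    ``bias`` is the function value at the constructed optimum when known
    (exactly, by construction, for shifted/rotated instances); ``optimum``
    is the optimum location when known.
    """

    name: str
    space: SearchSpace
    fn: Callable[[np.ndarray], np.ndarray]
    bias: float = 0.0
    optimum: Optional[np.ndarray] = None

    def evaluate_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.asarray(self.fn(X), dtype=float)

    def __call__(self, x) -> float:
        return float(self.evaluate_batch(np.asarray(x, float)[None, :])[0])


class BudgetExhausted(RuntimeError):
    """Raised when an evaluation is requested beyond MAX_FE."""


@dataclass
class EvaluationBudget:
    """Counter for function evaluations with a hard cap."""

    max_fe: int
    spent: int = 0

    @property
    def remaining(self) -> int:
        return self.max_fe - self.spent


def evaluate_with_budget(f: ObjectiveFunction, position,
                         budget: EvaluationBudget) -> float:
    """Evaluate one position, charging the budget; never over-spends."""
    if budget.spent >= budget.max_fe:
        raise BudgetExhausted(
            f"evaluation budget of {budget.max_fe} exhausted")
    value = f(position)
    budget.spent += 1
    return value


# ---------------------------------------------------------------------------
# Transformation builders
# ---------------------------------------------------------------------------

def make_rotation(dim: int, rng: RandomStream) -> np.ndarray:
    """Seeded Haar-orthogonal rotation matrix (QR of a Gaussian matrix)."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    g = rng.normal(size=(dim, dim))
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))
    return q


def load_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited numeric vector/matrix text file."""
    return np.loadtxt(path)


def _largest_remainder_split(dim: int, proportions: Sequence[float]) -> list[int]:
    raw = np.asarray(proportions) * dim
    sizes = np.floor(raw).astype(int)
    short = dim - sizes.sum()
    order = np.argsort(-(raw - sizes))
    for k in range(short):
        sizes[order[k]] += 1
    return sizes.tolist()


# CEC'20 catalogue: id -> (kind, spec). Hybrid spec: (proportions, bases,
# scales). Composition spec: (sigmas, lambdas, component biases, bases,
# scales).
CEC20_BIAS = {"f1": 100.0, "f2": 1100.0, "f3": 700.0, "f4": 1900.0,
              "f5": 1700.0, "f6": 1600.0, "f7": 2100.0, "f8": 2200.0,
              "f9": 2400.0, "f10": 2500.0}
CEC20_IDS = tuple(CEC20_BIAS)

_SINGLE = {
    "f1": (bent_cigar, 1.0),
    "f2": (schwefel, 10.0),
    "f3": (lunacek_bi_rastrigin, 0.1),
    "f4": (grie_rosen, 0.05),
}

_HYBRID = {
    "f5": ([0.3, 0.3, 0.4],
           [schwefel, rastrigin, elliptic],
           [10.0, 0.0512, 1.0]),
    "f6": ([0.2, 0.2, 0.3, 0.3],
           [schaffer_f6_expanded, hgbat, rosenbrock, schwefel],
           [1.0, 0.05, 0.02048, 10.0]),
    "f7": ([0.1, 0.2, 0.2, 0.2, 0.3],
           [schaffer_f6_expanded, hgbat, rosenbrock, schwefel, elliptic],
           [1.0, 0.05, 0.02048, 10.0, 1.0]),
}

_COMPOSITION = {
    "f8": ([10.0, 20.0, 30.0], [1.0, 10.0, 1.0], [0.0, 100.0, 200.0],
           [rastrigin, griewank, schwefel],
           [0.0512, 6.0, 10.0]),
    "f9": ([10.0, 20.0, 30.0, 40.0], [10.0, 1e-6, 10.0, 1.0],
           [0.0, 100.0, 200.0, 300.0],
           [ackley, elliptic, griewank, rastrigin],
           [1.0, 1.0, 6.0, 0.0512]),
    "f10": ([10.0, 20.0, 30.0, 40.0, 50.0], [10.0, 1.0, 10.0, 1e-6, 1.0],
            [0.0, 100.0, 200.0, 300.0, 400.0],
            [rastrigin, happycat, ackley, discus, rosenbrock],
            [0.0512, 0.05, 1.0, 1.0, 0.02048]),
}

_CEC_RANGE = 100.0
_HYBRID_DIMS = (5, 10, 15, 20)  # plus dim 2 for single-component functions


def _draw_shift(dim: int, rng: RandomStream) -> np.ndarray:
    return rng.uniform(-0.8 * _CEC_RANGE, 0.8 * _CEC_RANGE, dim)


def make_benchmark(fid: str, dim: int, rng: RandomStream | int | None = None,
                   data_dir=None) -> ObjectiveFunction:
    """Build a benchmark objective.

    Parameters
    ----------
    fid : str
        ``"f1"``..``"f10"`` for CEC'20-style instances on [-100, 100]^dim,
        or a plain base-function name (``"sphere"``, ``"rastrigin"``, ...)
        on its conventional symmetric range with optimum value 0.
    dim : int
        Dimensionality. CEC'20-style hybrid/composition ids require
        dim in {5, 10, 15, 20}; single-component ids also accept dim = 2.
    rng : RandomStream or int, optional
        Stream for the self-generated shift/rotation (default seed 0).
    data_dir : path, optional
        Directory of official whitespace-text data files
        (``shift_data_<k>.txt``, ``M_<k>_D<dim>.txt`` and, for hybrids,
        ``shuffle_data_<k>_D<dim>.txt``); overrides the seeded transforms.
    """
    fid = fid.lower()
    if rng is None:
        rng = RandomStream(0)
    elif isinstance(rng, (int, np.integer)):
        rng = RandomStream(int(rng))

    if fid in BASE_FUNCTIONS:
        b = _PLAIN_BOUNDS[fid]
        space = SearchSpace(dim, -b, b)
        base = BASE_FUNCTIONS[fid]
        return ObjectiveFunction(name=fid, space=space, fn=base, bias=0.0,
                                 optimum=np.zeros(dim))

    if fid not in CEC20_BIAS:
        raise ValueError(f"unknown benchmark id: {fid!r}")
    if fid in _SINGLE:
        if dim not in (2,) + _HYBRID_DIMS:
            raise ValueError(f"{fid} supports dim in {{2, 5, 10, 15, 20}}")
    elif dim not in _HYBRID_DIMS:
        raise ValueError(f"{fid} supports dim in {{5, 10, 15, 20}}")

    space = SearchSpace(dim, -_CEC_RANGE, _CEC_RANGE)
    bias = CEC20_BIAS[fid]
    k = int(fid[1:])
    stream = rng.child(f"cec20-{fid}-d{dim}")

    if fid in _SINGLE:
        base, scale = _SINGLE[fid]
        o, M = _load_or_draw(data_dir, k, dim, stream, n_rot=1)
        M = M[0]

        def fn(X, o=o, M=M, base=base, scale=scale, bias=bias):
            z = (X - o) @ M.T * scale
            return base(z) + bias

        return ObjectiveFunction(fid, space, fn, bias=bias, optimum=o.copy())

    if fid in _HYBRID:
        props, bases, scales = _HYBRID[fid]
        o, M = _load_or_draw(data_dir, k, dim, stream, n_rot=1)
        M = M[0]
        perm = _load_or_draw_shuffle(data_dir, k, dim, stream)
        sizes = _largest_remainder_split(dim, props)
        edges = np.cumsum([0] + sizes)

        def fn(X, o=o, M=M, perm=perm, bases=bases, scales=scales,
               edges=edges, bias=bias):
            z = (X - o) @ M.T
            z = z[:, perm]
            total = np.zeros(X.shape[0])
            for i, base in enumerate(bases):
                chunk = z[:, edges[i]:edges[i + 1]] * scales[i]
                total += base(chunk)
            return total + bias

        return ObjectiveFunction(fid, space, fn, bias=bias, optimum=o.copy())

    sigmas, lambdas, cbias, bases, scales = _COMPOSITION[fid]
    ncomp = len(bases)
    shifts, rots = _load_or_draw_composition(data_dir, k, dim, stream, ncomp)
    sigmas = np.asarray(sigmas)
    lambdas = np.asarray(lambdas)
    cbias_arr = np.asarray(cbias)

    def fn(X, shifts=shifts, rots=rots, bases=bases, scales=scales,
           sigmas=sigmas, lambdas=lambdas, cbias=cbias_arr, bias=bias,
           dim=dim):
        n = X.shape[0]
        g = np.empty((ncomp, n))
        d2 = np.empty((ncomp, n))
        for i, base in enumerate(bases):
            diff = X - shifts[i]
            d2[i] = np.sum(diff * diff, axis=1)
            z = diff @ rots[i].T * scales[i]
            g[i] = lambdas[i] * base(z) + cbias[i]
        with np.errstate(divide="ignore"):
            w = np.where(d2 > 0,
                         np.exp(-d2 / (2.0 * dim * sigmas[:, None] ** 2))
                         / np.sqrt(np.where(d2 > 0, d2, 1.0)),
                         np.inf)
        exact = d2 == 0
        hit = exact.any(axis=0)
        w[:, hit] = np.where(exact[:, hit], 1.0, 0.0)
        wsum = w.sum(axis=0)
        return np.sum(w / wsum * g, axis=0) + bias

    return ObjectiveFunction(fid, space, fn, bias=bias,
                             optimum=shifts[0].copy())


def _load_or_draw(data_dir, k, dim, stream, n_rot):
    if data_dir is not None:
        o = load_matrix(os.path.join(data_dir, f"shift_data_{k}.txt"))
        o = np.asarray(o, float).ravel()[:dim]
        M = load_matrix(os.path.join(data_dir, f"M_{k}_D{dim}.txt"))
        M = np.asarray(M, float).reshape(-1, dim)[: n_rot * dim]
        rots = M.reshape(n_rot, dim, dim)
    else:
        o = _draw_shift(dim, stream)
        rots = np.stack([make_rotation(dim, stream) for _ in range(n_rot)])
    _validate_transform(o, rots, dim)
    return o, rots


def _load_or_draw_shuffle(data_dir, k, dim, stream):
    if data_dir is not None:
        path = os.path.join(data_dir, f"shuffle_data_{k}_D{dim}.txt")
        perm = np.asarray(load_matrix(path), dtype=int).ravel()[:dim] - 1
    else:
        perm = stream.permutation(dim)
    if sorted(perm.tolist()) != list(range(dim)):
        raise ValueError("shuffle data is not a permutation of 1..dim")
    return perm


def _load_or_draw_composition(data_dir, k, dim, stream, ncomp):
    if data_dir is not None:
        o = load_matrix(os.path.join(data_dir, f"shift_data_{k}.txt"))
        o = np.atleast_2d(np.asarray(o, float))[:ncomp, :dim]
        M = load_matrix(os.path.join(data_dir, f"M_{k}_D{dim}.txt"))
        rots = np.asarray(M, float).reshape(-1, dim)[: ncomp * dim]
        rots = rots.reshape(ncomp, dim, dim)
    else:
        o = np.stack([_draw_shift(dim, stream) for _ in range(ncomp)])
        rots = np.stack([make_rotation(dim, stream) for _ in range(ncomp)])
    for i in range(ncomp):
        _validate_transform(o[i], rots[i][None, :, :], dim)
    return o, rots


def _validate_transform(o, rots, dim):
    if np.any(np.abs(o) >= _CEC_RANGE):
        raise ValueError("shift vector must lie strictly inside the bounds")
    for M in rots:
        err = np.max(np.abs(M @ M.T - np.eye(dim)))
        if err > 1e-10:
            raise ValueError(
                f"rotation matrix is not orthogonal (max |MMᵀ-I| = {err:.2e})")


def export_landscape_grid(f: ObjectiveFunction, path, n: int = 101) -> None:
    """Write an n×n CSV grid (x, y, f) of a 2-D objective for plotting."""
    if f.space.dim != 2:
        raise ValueError("landscape export requires a 2-D objective")
    xs = np.linspace(f.space.lower[0], f.space.upper[0], n)
    ys = np.linspace(f.space.lower[1], f.space.upper[1], n)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = f.evaluate_batch(pts)
    with open(path, "w") as fh:
        fh.write("x,y,f\n")
        for (x, y), v in zip(pts, vals):
            fh.write(f"{x!r},{y!r},{v!r}\n")
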