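"""Seeded simulation of MaxErlB variates.

A MaxErlB(k, lam, n, p) variate is generated exactly as the distribution
is constructed:

1. draw ``z* ~ Binom(n, p)``;
2. if ``z* = 0`` go back to step 1, else accept ``z = z*``
   (rejection sampling of the zero-truncated binomial);
3. draw ``z`` i.i.d. Erlang(k, lam) lifetimes, each as the sum of ``k``
   inverse-transform unit exponentials scaled by ``1/lam``;
4. return their maximum.

The default implementation vectorizes the per-draw loop: it pre-draws
``n`` Erlang lifetimes per accepted count and takes the maximum of the
first ``z`` of them, which is distributionally identical because the
lifetimes are i.i.d. and independent of ``z``.  The literal one-draw-at-
a-time loop is kept as ``method="loop"`` for cross-checking.  Both are
bit-reproducible given the same integer seed (NumPy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .distribution import MaxErlBParams
from .psd import sample_truncated_binomial

__all__ = ["SampleSet", "sample_erlang", "sample_maxerlb"]

_CHUNK = 1 << 20  # draws per vectorized block; bounds peak memory at m*n*k doubles


@dataclass(frozen=True)
class SampleSet:
    """An ordered collection of positive lifetimes with provenance.

    ``provenance`` records either the generating seed and parameters or
    the source file path, so a sample can always be traced back.
    """

    values: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("SampleSet requires a nonempty 1-d array of lifetimes")
        if not np.all(vals > 0):
            raise ValueError("all lifetimes must be strictly positive")
        object.__setattr__(self, "values", vals)

    @property
    def size(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.size


def sample_erlang(k: int, lam: float, count: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``count`` i.i.d. Erlang(k, lam) variates.

    Each variate is the sum of ``k`` unit exponentials obtained by
    inverse transform, ``-log(1 - U) / lam``, so the stream depends only
    on the underlying uniform generator and seed.
    """
    if k < 1 or int(k) != k:
        raise ValueError(f"Erlang shape k must be an integer >= 1; got {k}")
    if not lam > 0:
        raise ValueError(f"Erlang rate lam must be > 0; got {lam}")
    if count < 1:
        raise ValueError(f"count must be >= 1; got {count}")
    rng = np.random.default_rng(seed)
    u = rng.random(size=(count, k))
    return -np.log1p(-u).sum(axis=1) / lam


def _sample_vectorized(params: MaxErlBParams, m: int, rng: np.random.Generator) -> np.ndarray:
    k, lam, n = params.k, params.lam, params.n
    out = np.empty(m)
    for start in range(0, m, _CHUNK):
        size = min(_CHUNK, m - start)
        z = sample_truncated_binomial(n, params.p, size, rng)
        u = rng.random(size=(size, n, k))
        erl = -np.log1p(-u).sum(axis=2) / lam
        # mask components beyond the accepted count z before taking the max
        masked = np.where(np.arange(n) < z[:, None], erl, -np.inf)
        out[start : start + size] = masked.max(axis=1)
    return out


def _sample_loop(params: MaxErlBParams, m: int, rng: np.random.Generator) -> np.ndarray:
    # literal per-draw rejection loop, used as a reference implementation
    k, lam, n, p = params.k, params.lam, params.n, params.p
    out = np.empty(m)
    for j in range(m):
        z = 0
        while z == 0:
            z = int(rng.binomial(n, p))
        best = -np.inf
        for _ in range(z):
            x = -np.log1p(-rng.random(size=k)).sum() / lam
            best = max(best, x)
        out[j] = best
    return out


def sample_maxerlb(
    params: MaxErlBParams,
    m: int,
    seed: int | np.random.Generator,
    *,
    method: str = "vectorized",
) -> SampleSet:
    """Generate ``m`` MaxErlB(k, lam, n, p) variates.

    Identical seeds give identical samples for a given method; the
    empirical cdf converges to :func:`maxerlb.distribution.maxerlb_cdf`.
    """
    if m < 1:
        raise ValueError(f"sample size m must be >= 1; got {m}")
    rng = np.random.default_rng(seed)
    if method == "vectorized":
        values = _sample_vectorized(params, m, rng)
    elif method == "loop":
        values = _sample_loop(params, m, rng)
    else:
        raise ValueError(f"unknown method {method!r}; use 'vectorized' or 'loop'")
    provenance = {
        "seed": seed if isinstance(seed, int) else repr(seed),
        "generator": "numpy PCG64",
        "method": method,
        "params": {"k": params.k, "lam": params.lam, "n": params.n, "p": params.p},
    }
    return SampleSet(values=values, provenance=provenance)
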