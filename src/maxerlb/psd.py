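"""Zero-truncated power-series distribution (PSD) families.

A power-series distribution on the positive integers has pmf

    P(Z = z) = a_z * theta**z / A(theta),    z = 1, 2, ...

where the ``a_z`` are nonnegative coefficients, ``theta`` is the power
parameter, and ``A(theta) = sum_{z>=1} a_z theta**z`` is the series
function, finite for ``theta`` in ``(0, tau)``.  The compound-maximum
construction in :mod:`maxerlb.distribution` randomizes the number of
Erlang components over such a family; the zero-truncated binomial is the
family actually used by the MaxErlB distribution, and the only one with a
dedicated sampler here.

Registered families and their (a_z, theta, A, tau):

=================  =================  ===========  ====================  ====
name               a_z                theta        A(theta)              tau
=================  =================  ===========  ====================  ====
binomial(n)        C(n, z)            p/(1-p)      (1+theta)^n - 1       inf
poisson            1/z!               alpha        exp(theta) - 1        inf
logarithmic        1/z                p            -log(1-theta)         1
geometric          1                  1-p          theta/(1-theta)       1
pascal(k)          C(z-1, k-1)        1-p          (theta/(1-theta))^k   1
neg_binomial(k)    C(z+k-1, z)        p            (1-theta)^-k - 1      1
=================  =================  ===========  ====================  ====
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "PSDFamily",
    "binomial",
    "poisson",
    "logarithmic",
    "geometric",
    "pascal",
    "neg_binomial",
    "get_family",
    "psd_pmf",
    "series_eval",
    "sample_truncated_binomial",
    "theta_from_p",
    "p_from_theta",
    "truncated_binomial_mean",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSDFamily:
    """A zero-truncated power-series family.

    Parameters
    ----------
    name
        Family identifier (e.g. ``"binomial"``).
    coefficient
        Map ``z -> a_z`` for integer ``z >= 1``; zero outside the support.
    theta_radius
        Convergence radius ``tau`` of the series (may be ``inf``).
    series
        ``A(theta)``, its first and second derivative as a triple of
        callables.
    max_support
        Largest ``z`` with ``a_z > 0``; ``None`` for infinite support.
    shape_params
        Family-specific integer shapes (``n`` for the binomial, ``k`` for
        Pascal / negative binomial).
    """

    name: str
    coefficient: Callable[[int], float]
    theta_radius: float
    series: tuple[Callable[[float], float], ...]
    max_support: int | None = None
    shape_params: dict[str, int] = field(default_factory=dict)

    def _check_theta(self, theta: float) -> None:
        if not (0.0 < theta < self.theta_radius):
            raise ValueError(
                f"theta={theta} outside the open domain (0, {self.theta_radius}) "
                f"of family {self.name!r}"
            )

    def a(self, z: int) -> float:
        """Series coefficient ``a_z`` (0 outside the support)."""
        if z < 1:
            raise ValueError(f"PSD support starts at z=1; got z={z}")
        if self.max_support is not None and z > self.max_support:
            return 0.0
        return self.coefficient(z)

    def A(self, theta: float, order: int = 0) -> float:
        """Series function ``A`` or one of its first two derivatives."""
        self._check_theta(theta)
        if order not in (0, 1, 2):
            raise ValueError(f"order must be 0, 1 or 2; got {order}")
        return self.series[order](theta)

    def pmf(self, z: int, theta: float) -> float:
        """``P(Z = z) = a_z theta**z / A(theta)``."""
        self._check_theta(theta)
        if z < 1:
            raise ValueError(f"PSD support starts at z=1; got z={z}")
        az = self.a(z)
        if az == 0.0:
            return 0.0
        return az * theta**z / self.series[0](theta)

    def support(self, tail_mass: float = 1e-10, theta: float | None = None) -> np.ndarray:
        """Integer support, truncated where the tail mass drops below
        ``tail_mass`` for infinite-support families."""
        if self.max_support is not None:
            return np.arange(1, self.max_support + 1)
        if theta is None:
            raise ValueError("theta required to truncate an infinite support")
        zs = [1]
        total = self.pmf(1, theta)
        while 1.0 - total > tail_mass:
            zs.append(zs[-1] + 1)
            total += self.pmf(zs[-1], theta)
            if zs[-1] > 100_000:  # pragma: no cover - safety stop
                raise RuntimeError("support truncation did not converge")
        return np.asarray(zs)


def theta_from_p(p: float) -> float:
    """Power parameter of the truncated binomial: ``theta = p / (1 - p)``."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1); got p={p}")
    return p / (1.0 - p)


def p_from_theta(theta: float) -> float:
    """Inverse map ``p = theta / (1 + theta)``."""
    if theta <= 0:
        raise ValueError(f"theta must be positive; got {theta}")
    return theta / (1.0 + theta)


def binomial(n: int) -> PSDFamily:
    """Zero-truncated binomial Binom*(n, p), parameterized by theta = p/(1-p)."""
    if n < 1:
        raise ValueError(f"binomial size n must be >= 1; got {n}")
    return PSDFamily(
        name="binomial",
        coefficient=lambda z: float(math.comb(n, z)),
        theta_radius=math.inf,
        series=(
            lambda t: (1.0 + t) ** n - 1.0,
            lambda t: n * (1.0 + t) ** (n - 1),
            lambda t: n * (n - 1) * (1.0 + t) ** (n - 2),
        ),
        max_support=n,
        shape_params={"n": n},
    )


def poisson() -> PSDFamily:
    """Zero-truncated Poisson; theta is the Poisson mean."""
    return PSDFamily(
        name="poisson",
        coefficient=lambda z: 1.0 / math.factorial(z),
        theta_radius=math.inf,
        series=(lambda t: math.expm1(t), math.exp, math.exp),
    )


def logarithmic() -> PSDFamily:
    """Logarithmic series distribution; theta = p."""
    return PSDFamily(
        name="logarithmic",
        coefficient=lambda z: 1.0 / z,
        theta_radius=1.0,
        series=(
            lambda t: -math.log1p(-t),
            lambda t: 1.0 / (1.0 - t),
            lambda t: 1.0 / (1.0 - t) ** 2,
        ),
    )


def geometric() -> PSDFamily:
    """Geometric on {1, 2, ...}; theta = 1 - p."""
    return PSDFamily(
        name="geometric",
        coefficient=lambda z: 1.0,
        theta_radius=1.0,
        series=(
            lambda t: t / (1.0 - t),
            lambda t: 1.0 / (1.0 - t) ** 2,
            lambda t: 2.0 / (1.0 - t) ** 3,
        ),
    )


def pascal(k: int) -> PSDFamily:
    """Pascal (shifted negative binomial on {k, k+1, ...}); theta = 1 - p."""
    if k < 1:
        raise ValueError(f"Pascal shape k must be >= 1; got {k}")
    return PSDFamily(
        name="pascal",
        coefficient=lambda z: float(math.comb(z - 1, k - 1)) if z >= k else 0.0,
        theta_radius=1.0,
        series=(
            lambda t: (t / (1.0 - t)) ** k,
            lambda t: k * t ** (k - 1) / (1.0 - t) ** (k + 1),
            lambda t: k * t ** (k - 2) * ((k - 1) + 2 * t) / (1.0 - t) ** (k + 2),
        ),
        shape_params={"k": k},
    )


def neg_binomial(k: int) -> PSDFamily:
    """Zero-truncated negative binomial; theta = p."""
    if k < 1:
        raise ValueError(f"negative-binomial shape k must be >= 1; got {k}")
    return PSDFamily(
        name="neg_binomial",
        coefficient=lambda z: float(math.comb(z + k - 1, z)),
        theta_radius=1.0,
        series=(
            lambda t: (1.0 - t) ** (-k) - 1.0,
            lambda t: k * (1.0 - t) ** (-k - 1),
            lambda t: k * (k + 1) * (1.0 - t) ** (-k - 2),
        ),
        shape_params={"k": k},
    )


_FACTORIES: dict[str, Callable[..., PSDFamily]] = {
    "binomial": binomial,
    "poisson": poisson,
    "logarithmic": logarithmic,
    "geometric": geometric,
    "pascal": pascal,
    "neg_binomial": neg_binomial,
}


def get_family(name: str, **shape_params: int) -> PSDFamily:
    """Look up a registered family by name, passing its integer shapes."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown PSD family {name!r}; available: {sorted(_FACTORIES)}"
        ) from None
    return factory(**shape_params)


def psd_pmf(family: PSDFamily, z: int, theta: float) -> float:
    """Probability mass ``a_z theta**z / A(theta)`` of the family at ``z``."""
    return family.pmf(z, theta)


def series_eval(family: PSDFamily, theta: float, order: int = 0) -> float:
    """Evaluate ``A``, ``A'`` or ``A''`` at ``theta``."""
    return family.A(theta, order)


def sample_truncated_binomial(
    n: int, p: float, m: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``m`` variates from the zero-truncated binomial Binom*(n, p).

    Uses rejection sampling: draw Binom(n, p) and redraw any zeros.  The
    acceptance probability is ``1 - (1-p)**n`` per proposal; the realized
    rejection fraction is logged at DEBUG level.

    A fixed integer ``seed`` yields an identical sample on every call.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1; got {n}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1); got p={p}")
    if m < 1:
        raise ValueError(f"sample size m must be >= 1; got {m}")
    rng = np.random.default_rng(seed)
    out = rng.binomial(n, p, size=m)
    proposals = m
    zero = out == 0
    while zero.any():
        k = int(zero.sum())
        out[zero] = rng.binomial(n, p, size=k)
        proposals += k
        zero = out == 0
    logger.debug(
        "truncated-binomial rejection: %d proposals for %d draws "
        "(rejection fraction %.4f, expected %.4f)",
        proposals,
        m,
        1.0 - m / proposals,
        (1.0 - p) ** n,
    )
    return out


def truncated_binomial_mean(n: int, p: float) -> float:
    """Mean ``n p / (1 - (1-p)**n)`` of the zero-truncated binomial."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1); got p={p}")
    return n * p / -math.expm1(n * math.log1p(-p))
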