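"""EM estimation of (lam, p) for MaxErlB(k, lam, n, p) with k, n known.

The latent component count ``Z`` of each observed maximum is the missing
datum.  Writing ``w = F_Erl(x)`` for the Erlang cdf at an observation,
the conditional mean used in the E-step is, for the truncated-binomial
count family,

    E[Z | X = x] = 1 + (n - 1) p w / (1 - p (1 - w)),

which for k = 2, n = 3 reads
``1 + 2 p (1 - e^{-lam x}(1 + lam x)) / (1 - p e^{-lam x}(1 + lam x))``.
The same quantity follows from the generic power-series identity
``E[Z | X = x] = theta w A''(theta w) / A'(theta w) + 1``
(:func:`estep_generic`), and the two routes agree to machine precision.

Given expected counts ``z_j``, the complete-data log-likelihood
separates, so the M-step is two independent one-dimensional root finds:

* rate: ``k m / lam - sum x_j
  + sum (z_j - 1) x_j e^{-lam x_j} (lam x_j)^{k-1} / ((k-1)! F_Erl(x_j)) = 0``
  (for k = 2 the summand is ``lam x_j^2 e^{-lam x_j} /
  (1 - e^{-lam x_j}(1 + lam x_j))``);
* success probability: the score in ``p`` is equivalent to matching the
  truncated-binomial mean, ``n p / (1 - (1-p)^n) = mean(z_j)``, a
  strictly increasing function of ``p`` solved by bracketed bisection;
  the raw score is asserted to vanish at the root.

Iteration stops when ``max(|lam - lam_prev|, |p - p_prev|) <= epsilon``
or after ``max_iter`` sweeps.  The observed-data log-likelihood is
non-decreasing along the trace (EM ascent).  A direct numerical
maximizer of the observed-data log-likelihood (:func:`direct_mle`) is
provided as an independent cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .distribution import MaxErlBParams, erlang_cdf, maxerlb_logpdf
from .simulate import SampleSet

__all__ = [
    "EMConfig",
    "EMTrace",
    "FitResult",
    "observed_loglik",
    "estep",
    "estep_generic",
    "mstep",
    "em_fit",
    "direct_mle",
]


@dataclass(frozen=True)
class EMConfig:
    """EM controls: start point, stopping rule, solver tolerances.

    ``lam0 = None`` defaults to the Erlang moment-match ``k / mean(x)``
    (treating ``Z`` as if it were 1); ``p0`` defaults to the middle of
    its domain.  ``epsilon`` applies to the max absolute change of the
    two parameters between sweeps.
    """

    lam0: float | None = None
    p0: float = 0.5
    epsilon: float = 1e-6
    max_iter: int = 1000
    solver_xtol: float = 1e-12

    def __post_init__(self) -> None:
        if self.lam0 is not None and not self.lam0 > 0:
            raise ValueError(f"lam0 must be > 0; got {self.lam0}")
        if not (0.0 < self.p0 < 1.0):
            raise ValueError(f"p0 must lie in (0, 1); got {self.p0}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0; got {self.epsilon}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1; got {self.max_iter}")


@dataclass
class EMTrace:
    """Per-iteration history: parameters, log-likelihood, E-step summary."""

    lam: list[float] = field(default_factory=list)
    p: list[float] = field(default_factory=list)
    loglik: list[float] = field(default_factory=list)
    z_mean: list[float] = field(default_factory=list)
    z_min: list[float] = field(default_factory=list)
    z_max: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class FitResult:
    """Final EM estimates with convergence status and iteration trace."""

    lam: float
    p: float
    converged: bool
    iterations: int
    loglik: float
    trace: EMTrace

    @property
    def estimates(self) -> tuple[float, float]:
        return (self.lam, self.p)


def _values(sample: SampleSet | np.ndarray) -> np.ndarray:
    x = sample.values if isinstance(sample, SampleSet) else np.asarray(sample, dtype=float)
    if np.any(x <= 1e-12):
        raise ValueError("all observations must be strictly positive (> 1e-12)")
    return x


def observed_loglik(sample: SampleSet | np.ndarray, params: MaxErlBParams) -> float:
    """Observed-data log-likelihood ``sum_j log f(x_j; params)``."""
    return float(np.sum(maxerlb_logpdf(_values(sample), params)))


def estep(sample: SampleSet | np.ndarray, params: MaxErlBParams) -> np.ndarray:
    """Conditional mean ``E[Z | X = x_j]`` of the latent count, per observation.

    Closed form for the truncated-binomial family; always in ``[1, n]``
    and increasing in ``x``.
    """
    x = _values(sample)
    w = erlang_cdf(x, params.k, params.lam)
    return 1.0 + (params.n - 1) * params.p * w / (1.0 - params.p * (1.0 - w))


def estep_generic(sample: SampleSet | np.ndarray, params: MaxErlBParams) -> np.ndarray:
    """E-step via the power-series identity ``theta w A''(theta w)/A'(theta w) + 1``.

    Uses the family's series derivatives directly; agrees with
    :func:`estep` to machine precision for the binomial family.
    """
    x = _values(sample)
    w = erlang_cdf(x, params.k, params.lam)
    _, A1, A2 = params.family.series
    tw = params.theta * w
    a1 = np.vectorize(A1, otypes=[float])(tw)
    a2 = np.vectorize(A2, otypes=[float])(tw)
    return tw * a2 / a1 + 1.0


def _lam_score(lam: float, x: np.ndarray, z: np.ndarray, k: int) -> float:
    """Complete-data score in the rate, at fixed expected counts z.

    The Erlang cdf is expanded as its finite exponential sum (k is a
    small integer), which is much cheaper than the incomplete gamma
    function inside a root-finding loop; ``-expm1`` keeps the small-x
    cancellation mild.
    """
    lx = lam * x
    e = np.exp(-lx)
    tail = np.zeros_like(lx)  # e^{-lx} * sum_{i=1}^{k-1} (lx)^i / i!
    term = np.ones_like(lx)
    for i in range(1, k):
        term = term * lx / i
        tail += term
    w = -np.expm1(-lx) - e * tail  # F_Erl(x); cancellation O(eps/lx)
    dens = x * e * term / w  # term == (lx)^{k-1}/(k-1)! after the loop
    return float(k * x.size / lam - x.sum() + np.sum((z - 1.0) * dens))


def _p_score(p: float, z_sum: float, m: int, n: int) -> float:
    """Raw complete-data score in p (the printed form, kept as a check)."""
    q = 1.0 - p
    return -n * m * q ** (n - 1) / (1.0 - q**n) - n * m / q + z_sum / (p * q)


def _solve_p(z_bar: float, n: int, xtol: float) -> float:
    """Root of the moment equation ``n p / (1 - (1-p)^n) = z_bar``."""

    def g(p: float) -> float:
        return n * p / -math.expm1(n * math.log1p(-p)) - z_bar

    lo, hi = 1e-12, 1.0 - 1e-12
    if g(lo) > 0 or z_bar <= 1.0 + 1e-10:
        raise ValueError(
            f"degenerate M-step: mean latent count {z_bar:.6g} is at the p -> 0 "
            "boundary (all observations behave like single-component systems)"
        )
    if g(hi) < 0:
        raise ValueError(
            f"degenerate M-step: mean latent count {z_bar:.6g} is at the p -> 1 boundary"
        )
    return float(optimize.brentq(g, lo, hi, xtol=xtol, rtol=8.9e-16))


def mstep(
    sample: SampleSet | np.ndarray,
    z: np.ndarray,
    previous: MaxErlBParams,
    config: EMConfig | None = None,
) -> tuple[float, float]:
    """Maximize the complete-data likelihood at expected counts ``z``.

    Returns the updated ``(lam, p)``: the rate solves the complete-data
    score by bracketed root finding (bracket grown around the previous
    rate), the success probability solves the truncated-binomial moment
    equation.  Raises when a bracket has no sign change or the latent
    mean sits on a boundary.
    """
    config = config or EMConfig()
    x = _values(sample)
    z = np.asarray(z, dtype=float)
    if z.shape != x.shape:
        raise ValueError("z must have one expected count per observation")
    if np.any(z < 1.0 - 1e-9) or np.any(z > previous.n + 1e-9):
        raise ValueError(f"expected counts must lie in [1, n={previous.n}]")
    k, n, m = previous.k, previous.n, x.size

    # EM rate updates are local, so a bracket around the previous rate is
    # almost always enough; it is widened geometrically if not
    lo, hi = previous.lam / 2.0, previous.lam * 2.0
    f_lo, f_hi = _lam_score(lo, x, z, k), _lam_score(hi, x, z, k)
    grow = 0
    while f_lo * f_hi > 0:
        lo /= 8.0
        hi *= 8.0
        f_lo, f_hi = _lam_score(lo, x, z, k), _lam_score(hi, x, z, k)
        grow += 1
        if grow > 50:
            raise RuntimeError(
                f"no sign change for the rate score on [{lo:g}, {hi:g}]: "
                f"score({lo:g})={f_lo:g}, score({hi:g})={f_hi:g}"
            )
    lam_new = float(
        optimize.brentq(
            _lam_score, lo, hi, args=(x, z, k), xtol=config.solver_xtol, rtol=8.9e-16
        )
    )
    p_new = _solve_p(float(z.mean()), n, config.solver_xtol)
    return lam_new, p_new


def em_fit(
    sample: SampleSet | np.ndarray,
    config: EMConfig | None = None,
    k: int = 2,
    n: int = 3,
) -> FitResult:
    """Fit (lam, p) by EM with ``k`` and ``n`` known.

    Alternates :func:`estep` and :func:`mstep` from ``(lam0, p0)`` until
    the parameter change drops below ``epsilon`` or ``max_iter`` is hit;
    non-convergence is reported in the result, not raised.
    """
    config = config or EMConfig()
    x = _values(sample)
    lam = config.lam0 if config.lam0 is not None else k / float(x.mean())
    p = config.p0
    trace = EMTrace()
    converged = False
    h = 0
    for h in range(1, config.max_iter + 1):
        params = MaxErlBParams(k=k, lam=lam, n=n, p=p)
        z = estep(x, params)
        try:
            lam_new, p_new = mstep(x, z, params, config)
        except ValueError as err:
            raise ValueError(f"M-step failed at iteration {h}: {err}") from err
        trace.lam.append(lam_new)
        trace.p.append(p_new)
        trace.loglik.append(observed_loglik(x, MaxErlBParams(k=k, lam=lam_new, n=n, p=p_new)))
        trace.z_mean.append(float(z.mean()))
        trace.z_min.append(float(z.min()))
        trace.z_max.append(float(z.max()))
        delta = max(abs(lam_new - lam), abs(p_new - p))
        lam, p = lam_new, p_new
        if delta <= config.epsilon:
            converged = True
            break
    return FitResult(
        lam=lam,
        p=p,
        converged=converged,
        iterations=h,
        loglik=trace.loglik[-1],
        trace=trace,
    )


def direct_mle(
    sample: SampleSet | np.ndarray,
    k: int = 2,
    n: int = 3,
    init: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Maximize the observed-data log-likelihood numerically over (lam, p).

    Independent of the EM route; optimizes in (log lam, logit p) with
    Nelder-Mead.  For ``n = 1`` the model is a plain Erlang, ``p`` is
    unidentified, and ``(k / mean(x), nan)`` is returned with a warning.
    """
    x = _values(sample)
    if n == 1:
        warnings.warn(
            "n = 1: MaxErlB reduces to Erlang(k, lam); p is unidentified",
            stacklevel=2,
        )
        return k / float(x.mean()), math.nan
    lam0, p0 = init if init is not None else (k / float(x.mean()), 0.5)

    def negll(v: np.ndarray) -> float:
        lam = math.exp(v[0])
        p = 1.0 / (1.0 + math.exp(-v[1]))
        return -observed_loglik(x, MaxErlBParams(k=k, lam=lam, n=n, p=p))

    v0 = np.array([math.log(lam0), math.log(p0 / (1.0 - p0))])
    res = optimize.minimize(
        negll, v0, method="Nelder-Mead", options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 2000}
    )
    if not res.success:
        raise RuntimeError(f"direct likelihood maximization failed: {res.message}")
    return float(math.exp(res.x[0])), float(1.0 / (1.0 + math.exp(-res.x[1])))
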