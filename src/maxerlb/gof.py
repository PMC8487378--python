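"""Pearson chi-square concordance test against a MaxErlB distribution.

The sample is binned into ``r`` intervals ``[t_{j-1}, t_j)`` spanning
``(0, inf)``; under the null the model assigns each bin probability
``p_j = F(t_j) - F(t_{j-1})``.  The statistic

    chi2_c = sum_j (n_j - n_0 p_j)^2 / (n_0 p_j)

is referred to the upper-``alpha`` critical value of the chi-square
distribution with ``(r - 1) - L`` degrees of freedom, ``L`` being the
number of parameters counted as estimated.  The null is rejected when
the statistic exceeds the critical value.

Default binning uses ``r`` equal-probability intervals from the model
quantile function; adjacent bins are merged greedily (smallest combined
expected count first) until every expected count ``n_0 p_j`` reaches the
standard Pearson threshold of 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distribution import MaxErlBParams, maxerlb_cdf, maxerlb_quantile
from .simulate import SampleSet

__all__ = [
    "GOFResult",
    "bin_probabilities",
    "chisq_statistic",
    "merge_bins",
    "equal_probability_bins",
    "chi2_critical_value",
    "run_gof",
]


@dataclass(frozen=True)
class GOFResult:
    """Outcome of the Pearson test: binning, statistic, and decision."""

    bin_ends: np.ndarray  # t_0 = 0 < t_1 < ... < t_r = inf
    observed: np.ndarray  # counts n_j
    expected_probs: np.ndarray  # model probabilities p_j
    statistic: float
    df: int
    alpha: float
    critical: float
    reject: bool

    @property
    def n_bins(self) -> int:
        return int(self.observed.size)

    @property
    def n_total(self) -> int:
        return int(self.observed.sum())

    def to_dict(self) -> dict:
        return {
            "bin_ends": [float(t) for t in self.bin_ends],
            "observed": [int(c) for c in self.observed],
            "expected_probs": [float(p) for p in self.expected_probs],
            "statistic": float(self.statistic),
            "df": int(self.df),
            "alpha": float(self.alpha),
            "critical": float(self.critical),
            "reject": bool(self.reject),
        }


def _check_bin_ends(bin_ends: np.ndarray) -> np.ndarray:
    ends = np.asarray(bin_ends, dtype=float)
    if ends.ndim != 1 or ends.size < 2:
        raise ValueError("bin_ends must be a 1-d array with at least two entries")
    if not np.all(np.diff(ends) > 0):
        raise ValueError("bin_ends must be strictly increasing")
    if ends[0] != 0.0 or not np.isinf(ends[-1]):
        raise ValueError("bins must span (0, inf): t_0 = 0 and t_r = inf")
    return ends


def bin_probabilities(bin_ends, params: MaxErlBParams) -> np.ndarray:
    """Model probabilities ``p_j = F(t_j) - F(t_{j-1})`` for each bin."""
    ends = _check_bin_ends(bin_ends)
    cdf = np.empty_like(ends)
    finite = np.isfinite(ends)
    cdf[finite] = maxerlb_cdf(ends[finite], params)
    cdf[~finite] = 1.0
    return np.diff(cdf)


def chisq_statistic(observed, expected_probs) -> float:
    """Pearson statistic ``sum (n_j - n_0 p_j)^2 / (n_0 p_j)``."""
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape:
        raise ValueError("observed and expected_probs must have the same length")
    n0 = obs.sum()
    if n0 <= 0:
        raise ValueError("total observed count must be positive")
    if not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValueError(f"expected probabilities must sum to 1; got {probs.sum()}")
    expected = n0 * probs
    if np.any(expected <= 0):
        raise ValueError("every expected count must be positive; merge bins first")
    return float(((obs - expected) ** 2 / expected).sum())


def merge_bins(
    bin_ends, observed, expected_probs, min_expected: float = 5.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge adjacent bins until every expected count reaches ``min_expected``.

    Greedy rule: repeatedly merge the adjacent pair with the smallest
    combined expected count.  Counts and probabilities add; the shared
    interior endpoint is dropped.
    """
    ends = list(_check_bin_ends(bin_ends))
    obs = list(np.asarray(observed, dtype=float))
    probs = list(np.asarray(expected_probs, dtype=float))
    if not (len(ends) - 1 == len(obs) == len(probs)):
        raise ValueError("inconsistent binning: need len(bin_ends) - 1 counts and probs")
    n0 = sum(obs)
    while len(obs) > 1 and min(n0 * q for q in probs) < min_expected:
        pair_tot = [probs[i] + probs[i + 1] for i in range(len(probs) - 1)]
        i = int(np.argmin(pair_tot))
        obs[i : i + 2] = [obs[i] + obs[i + 1]]
        probs[i : i + 2] = [probs[i] + probs[i + 1]]
        del ends[i + 1]
    if min(n0 * q for q in probs) < min_expected:
        raise ValueError(
            f"cannot reach expected count {min_expected} with at least two bins "
            f"(n_0 = {n0:g})"
        )
    return np.asarray(ends), np.asarray(obs), np.asarray(probs)


def equal_probability_bins(params: MaxErlBParams, r: int) -> np.ndarray:
    """``r`` bins of equal model probability 1/r from the quantile function."""
    if r < 2:
        raise ValueError(f"need at least 2 bins; got r={r}")
    interior = maxerlb_quantile(np.arange(1, r) / r, params)
    return np.concatenate(([0.0], np.atleast_1d(interior), [np.inf]))


def chi2_critical_value(alpha: float, df: int) -> float:
    """Upper-``alpha`` quantile of chi-square with ``df`` degrees of freedom."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1); got {alpha}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1; got {df}")
    return float(stats.chi2.isf(alpha, df))


def run_gof(
    sample: SampleSet,
    params: MaxErlBParams,
    r: int = 12,
    L: int = 4,
    alpha: float = 0.05,
    min_expected: float = 5.0,
) -> GOFResult:
    """Full Pearson test of ``sample`` against MaxErlB(``params``).

    Builds ``r`` equal-probability bins, merges small-expectation bins,
    computes the statistic and compares it with the upper-``alpha``
    chi-square critical value at ``df = (r_merged - 1) - L``.
    """
    values = sample.values
    ends = equal_probability_bins(params, r)
    probs = bin_probabilities(ends, params)
    observed, _ = np.histogram(values, bins=np.concatenate((ends[:-1], [np.inf])))
    ends, observed, probs = merge_bins(ends, observed, probs, min_expected)
    # renormalize away quadrature-level rounding so the statistic is exact
    probs = probs / probs.sum()
    statistic = chisq_statistic(observed, probs)
    df = (len(observed) - 1) - L
    if df < 1:
        raise ValueError(
            f"degrees of freedom {(len(observed) - 1)} - {L} < 1 after merging"
        )
    critical = chi2_critical_value(alpha, df)
    return GOFResult(
        bin_ends=ends,
        observed=observed.astype(int),
        expected_probs=probs,
        statistic=statistic,
        df=df,
        alpha=alpha,
        critical=critical,
        reject=bool(statistic > critical),
    )
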