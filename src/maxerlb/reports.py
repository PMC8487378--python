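"""Machine-readable JSON reports emitted by the CLI.

Every report is a pydantic model, so construction validates types and
finiteness; the corresponding JSON Schemas are shipped under
``maxerlb/schemas/`` and kept in sync by the test suite.  Infinite bin
ends (the last chi-square bin is unbounded) are serialized as ``null``
so every number in a report is finite.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, field_validator

from .em import FitResult
from .gof import GOFResult

__all__ = ["ParamsReport", "MomentsReport", "GofReport", "FitReport", "DemoReport"]


class _Finite(BaseModel):
    @field_validator("*")
    @classmethod
    def _finite(cls, v):
        if isinstance(v, float) and not math.isfinite(v):
            raise ValueError("numeric report fields must be finite")
        return v


class ParamsReport(_Finite):
    k: int
    lam: float
    n: int
    p: float


class MomentsReport(_Finite):
    params: ParamsReport
    mean: float
    variance: float


class GofReport(_Finite):
    params: ParamsReport
    sample_size: int
    bin_ends: list[float | None]  # null marks the unbounded upper end
    observed: list[int]
    expected_probs: list[float]
    statistic: float
    df: int
    alpha: float
    critical: float
    reject: bool

    @classmethod
    def from_result(cls, result: GOFResult, params: ParamsReport) -> "GofReport":
        ends = [None if math.isinf(t) else float(t) for t in result.bin_ends]
        return cls(
            params=params,
            sample_size=result.n_total,
            bin_ends=ends,
            observed=[int(c) for c in result.observed],
            expected_probs=[float(q) for q in result.expected_probs],
            statistic=result.statistic,
            df=result.df,
            alpha=result.alpha,
            critical=result.critical,
            reject=result.reject,
        )


class FitReport(_Finite):
    k: int
    n: int
    lam_hat: float
    p_hat: float
    converged: bool
    iterations: int
    loglik: float

    @classmethod
    def from_result(cls, result: FitResult, k: int, n: int) -> "FitReport":
        return cls(
            k=k,
            n=n,
            lam_hat=result.lam,
            p_hat=result.p,
            converged=result.converged,
            iterations=result.iterations,
            loglik=result.loglik,
        )


class DemoReport(_Finite):
    dataset: str
    fit: FitReport
    gof: GofReport
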