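import numpy as np
import pytest

from maxerlb import MaxErlBParams


@pytest.fixture(scope="session")
def params_ref() -> MaxErlBParams:
    """Reference parameter set used throughout the simulation study."""
    return MaxErlBParams(k=2, lam=10.0, n=3, p=0.2)


@pytest.fixture(scope="session")
def params_em() -> MaxErlBParams:
    """Parameter set of the EM recovery study."""
    return MaxErlBParams(k=2, lam=1.0, n=3, p=0.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def mixture_cdf(x, params: MaxErlBParams) -> float:
    """Independent oracle: F(x) = sum_z P(Z=z) F_Erl(x)^z over the
    truncated-binomial weights."""
    from maxerlb import erlang_cdf, psd_pmf

    fam = params.family
    w = erlang_cdf(x, params.k, params.lam)
    return sum(
        psd_pmf(fam, z, params.theta) * w**z for z in range(1, params.n + 1)
    )
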