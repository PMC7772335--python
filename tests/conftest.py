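import numpy as np
import pytest

from demosfs import ScaledParams, make_model_spec


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def asymig_spec():
    return make_model_spec("ASYMIG")


@pytest.fixture(scope="session")
def asymig_truth():
    """Realistic Europe/Africa-style ASYMIG parameters (autosomal scale):
    a ~4x expanded ancestral-range population, a ~9% founder bottleneck
    with recovery, split ~0.175 and expansion ~0.55 coalescent time units,
    asymmetric gene flow stronger into the ancestral range."""
    return ScaledParams(
        nu_af=4.083,
        nu_bot=0.0892,
        nu_eu=0.875,
        T_exp=0.5511,
        T_split=0.17504,
        M_AtoE=0.4,
        M_EtoA=1.23,
    )


@pytest.fixture(scope="session")
def constant_pop():
    """NOMIG parameterization equivalent to one constant-size population."""
    from demosfs import constant_population_params

    return constant_population_params()
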