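import numpy as np
import pytest

from crtsubgroup import DesignParams, EffectSpec


@pytest.fixture
def umdex_design() -> DesignParams:
    """Worked-example exercise CRT: 10 residents/cluster, 36% subgroup prevalence."""
    return DesignParams(
        m=10, pi=0.5, p1=0.36, sigma2=1.0, rho_y=0.04, rho_s=0.2, alpha=0.05
    )


@pytest.fixture
def umdex_effect() -> EffectSpec:
    return EffectSpec(delta0=0.7, delta1=0.5)


@pytest.fixture
def table1_design() -> DesignParams:
    """First simulation-grid scenario for the omnibus test."""
    return DesignParams(m=20, pi=0.5, p1=0.5, sigma2=1.0, rho_y=0.02, rho_s=0.10)


@pytest.fixture
def table1_effect() -> EffectSpec:
    return EffectSpec(delta0=0.2, delta1=0.3)


@pytest.fixture
def table2_effect() -> EffectSpec:
    return EffectSpec(delta0=0.3, delta1=0.4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
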