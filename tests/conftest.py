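import numpy as np
import pytest

from aahub import (
    ChemicalModelParams,
    StabilityParams2D,
    ThermalModelParams,
    stability_preset,
)


@pytest.fixture
def taf4_2d() -> StabilityParams2D:
    """Published 2D global-analysis parameters of the AtTAF4 RST domain."""
    return stability_preset("AtTAF4-RST")["twod"]


@pytest.fixture
def rcd1_2d() -> StabilityParams2D:
    """Published 2D global-analysis parameters of the AtRCD1 RST domain."""
    return stability_preset("AtRCD1-RST")["twod"]


@pytest.fixture
def thermal_truth() -> ThermalModelParams:
    """A sharp, well-determined thermal transition with sloping baselines."""
    return ThermalModelParams(250.0, 341.15, (1.0, -0.001), (0.2, 0.0005))


@pytest.fixture
def chemical_truth() -> ChemicalModelParams:
    return ChemicalModelParams(7.0, 3.7, (1.0, 0.01), (0.2, -0.005))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
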