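import numpy as np
import pytest

from thermoloc import HeatSource, TissueParams


@pytest.fixture
def tissue() -> TissueParams:
    """Default tissue constants (27 degC ambient)."""
    return TissueParams()


@pytest.fixture
def tissue_26_6() -> TissueParams:
    """Tissue constants with the 26.6 degC ambient of the
    temperature-sensitivity reference case."""
    return TissueParams().with_env_C(26.6)


@pytest.fixture
def sensitivity_source() -> HeatSource:
    """Reference source of the sensitivity studies: 0.045 W, 1.05 cm, 5 mm."""
    return HeatSource(Q=0.045, d=0.0105, R=0.005)


@pytest.fixture
def point_fixture_source() -> HeatSource:
    """Point source used as the inversion round-trip fixture."""
    return HeatSource(Q=0.1, d=0.014, R=0.0)


@pytest.fixture
def wide_offsets() -> np.ndarray:
    """Lateral scan from -0.1 m to +0.1 m through the hotspot."""
    return np.linspace(-0.1, 0.1, 401)
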