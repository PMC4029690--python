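import pytest

from isfextract import ElectrodeNetwork, ExtractionConfig, SkinPermeability


@pytest.fixture
def fixture_net() -> ElectrodeNetwork:
    """Reference seven-resistor network used across the suite (kΩ)."""
    return ElectrodeNetwork(r_a=100.0, r_b=50.0, r_c=80.0, r_1=20.0, r_2=30.0,
                            r_3=10000.0, r_4=10000.0)


@pytest.fixture
def cfg() -> ExtractionConfig:
    """Standard extraction chamber: 50 μL buffer, 10 min, 0.785 cm², k=1."""
    return ExtractionConfig()


@pytest.fixture
def skin() -> SkinPermeability:
    """Calibrated skin permeability: C1 = 500 μL·kΩ (5 μL at 100 kΩ)."""
    return SkinPermeability(c1=500.0)
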