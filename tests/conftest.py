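import numpy as np
import pytest

from myorescue.splicemodel import default_model, preset_model, toy_clcn1_gene


@pytest.fixture(scope="session")
def gene():
    return toy_clcn1_gene()


@pytest.fixture(scope="session")
def ko_model():
    return preset_model("Mbnl1KO")


@pytest.fixture(scope="session")
def adr_model():
    return preset_model("ADR")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def one_event_model():
    """Single frame-disrupting event, p = 0.5, δ = 0.2."""
    return default_model(
        {"I2": 0.0, "E7a": 0.5, "I6": 0.0, "E8a": 0.0}, nmd_survival=0.2
    )
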