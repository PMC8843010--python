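import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def quiet_plant():
    """Noise-free default plant for deterministic closed-loop checks."""
    from anklesim import AnklePlant, PlantParams
    return AnklePlant(PlantParams(noise_sd=0.0))


@pytest.fixture
def controller_params():
    from anklesim import ControllerParams
    return ControllerParams()


class FixedPatient:
    """Patient stub with constant per-muscle capacities."""

    def __init__(self, pf=0.0, df=0.0):
        self.pf, self.df = pf, df

    def capacity(self, muscle, day):
        return self.pf if muscle == "pf" else self.df


@pytest.fixture
def zero_patient():
    return FixedPatient(0.0, 0.0)
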