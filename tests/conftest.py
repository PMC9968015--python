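import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from optonose import DyeFormulation, SensorPanel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def panel8():
    spots = tuple(
        DyeFormulation(dye_id=f"D{i}", base_dye=f"base{i}", solvent="ethanol")
        for i in range(8)
    )
    return SensorPanel(panel_id="P1", spots=spots)
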