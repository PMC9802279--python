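import numpy as np
import pytest

import matecalcium as mc


@pytest.fixture
def simple_ethogram() -> mc.Ethogram:
    """Hand-built valid ethogram matching the worked metric example:
    ventral contact [0, 120], vulva contact [40, 50], 2 successful +
    1 failed turn, one ejaculation at 49 s."""
    return mc.Ethogram(
        recording_id="ex",
        duration_s=120.0,
        intervals={
            "ventral_contact": [(0.0, 120.0)],
            "vulva_contact": [(40.0, 50.0)],
            "backward_slide": [(0.0, 30.0), (60.0, 80.0)],
            "forward_slide": [(30.0, 40.0)],
        },
        points={
            "turn_success": [30.0, 80.0],
            "turn_fail": [100.0],
            "ejaculation": [49.0],
            "spicule_insertion": [48.5],
        },
    )


@pytest.fixture
def small_config() -> mc.SimulationConfig:
    return mc.SimulationConfig(recording_duration_s=120.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
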