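import numpy as np
import pytest
from hypothesis import settings

from hypnomarkov.hypnogram_io import Hypnogram

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy_fine() -> Hypnogram:
    """10-epoch worked example covering all four stage classes."""
    return Hypnogram(
        subject_id="toy",
        group="HC-VEH",
        stages=("AW", "AW", "SWS1", "SWS1", "SWS2", "IS", "REM", "REM", "PW", "SWS1"),
    )


@pytest.fixture
def two_state_hypnogram() -> Hypnogram:
    return Hypnogram(
        subject_id="w", group="HC-VEH", stages=("WAKE", "WAKE", "SLEEP", "SLEEP", "WAKE")
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
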