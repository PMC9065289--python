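import numpy as np
import pytest

from nqokinetics import RateLawParams
from nqokinetics import simulate as sim


@pytest.fixture(scope="session")
def human_truth() -> RateLawParams:
    return sim.PRESET_TRUTHS["human_bnah"]


@pytest.fixture(scope="session")
def duck_truth() -> RateLawParams:
    return sim.PRESET_TRUTHS["duck_bnah"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def replicate_seeds(master: int, n: int) -> np.ndarray:
    """Independent child seeds below 2**31, reproducible from one master seed."""
    return np.random.SeedSequence(master).generate_state(n) % (2**31)
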