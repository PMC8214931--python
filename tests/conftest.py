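import pytest

from stayhome.config import TrueParams, WorldConfig, load_holidays
from stayhome.synthetic import generate_world


@pytest.fixture(scope="session")
def holidays():
    return load_holidays()


@pytest.fixture(scope="session")
def zero_noise_world():
    """Small fully-deterministic world: behavior layer has no noise, mesh
    counts are exact, so every downstream stage can be checked as an
    identity."""
    cfg = WorldConfig(
        n_prefectures=6,
        n_regions=2,
        end="2020-03-31",
        seed=3,
        meshes_per_cell=3,
    )
    return generate_world(cfg, TrueParams(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_world():
    """Mid-size world with behavioral noise at the default level."""
    cfg = WorldConfig(
        n_prefectures=12,
        n_regions=2,
        end="2020-06-03",
        seed=11,
        meshes_per_cell=3,
    )
    return generate_world(cfg, TrueParams(), make_meshes=False)
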