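import numpy as np
import pytest

from flywell.synthgen import SimParams, generate_session, make_layout


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Desk-scale session: 4 wells, 10 s — enough structure for geometry
    and detection tests without rendering minutes of video."""
    return SimParams(n_wells=4, duration_s=10.0, p_roam_to_food=0.05, p_food_to_roam=0.02)


@pytest.fixture(scope="session")
def small_layout(small_params):
    return make_layout(small_params)


@pytest.fixture(scope="session")
def small_session(small_params):
    return generate_session(small_params, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
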