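import numpy as np
import pytest

from omr_assay import (
    ArenaGeometry,
    FrameStack,
    LarvaBehaviorParams,
    build_lane_map,
    render_synthetic_stack,
    simulate_trajectories,
)


@pytest.fixture(scope="session")
def geometry():
    return ArenaGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """Five-lane arena: cheap to render, same physics as the full one."""
    return ArenaGeometry(lane_count=5)


@pytest.fixture(scope="session")
def small_sim(small_geometry):
    """One-round simulation of always-responding larvae plus its clean stack."""
    params = LarvaBehaviorParams(response_prob=1.0, seed=7)
    truth = simulate_trajectories(small_geometry, params, rounds=1)
    stack = render_synthetic_stack(truth, noise_sd=0.0)
    return truth, stack


@pytest.fixture(scope="session")
def small_lanes(small_geometry):
    return build_lane_map(small_geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
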