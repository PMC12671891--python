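import numpy as np
import pytest

from chaseambush import AgentTrait, WorldConfig, make_fixture, run


@pytest.fixture(scope="session")
def fast_plan():
    return make_fixture("fast")


@pytest.fixture(scope="session")
def tiny_world():
    """A very small world for property tests that need many short runs."""
    return WorldConfig(
        world_width=15,
        world_height=15,
        grass_regrowth_time=15,
        initial_sheep=30,
        initial_wolves=8,
        c_b=0.02,
        r=3.6,
        horizon=150,
        window=(100, 150),
    )


@pytest.fixture(scope="session")
def sensory_traits():
    prey = AgentTrait(role="prey", algorithm="sensory", S=0.0, d=0.2)
    pred = AgentTrait(role="predator", algorithm="sensory", S=0.0, d=0.2)
    return prey, pred


@pytest.fixture(scope="session")
def tiny_run(tiny_world, sensory_traits):
    prey, pred = sensory_traits
    return run(tiny_world, prey, pred, seed=7, record_events=True)
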