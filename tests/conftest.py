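import numpy as np
import pytest

from lhonsim.diffusion_engine import SimulationParams
from lhonsim.experiments import StudyConfig, repeat_study
from lhonsim.nerve_geometry import build_nerve


@pytest.fixture(scope="session")
def tiny_nerve():
    """~480 axons, 300x300 grid; cheap enough for brute-force oracles."""
    return build_nerve(scale=0.02, rng_seed=7)


@pytest.fixture(scope="session")
def small_nerve():
    """~1,900 axons, 600x600 grid; used for engine-level behavior tests."""
    return build_nerve(scale=0.04, rng_seed=11)


@pytest.fixture(scope="session")
def small_params():
    """Constants for quick small-nerve runs (bounded iteration budget)."""
    return SimulationParams(max_iterations=4000)


@pytest.fixture(scope="session")
def reference_study():
    """The repetition study at reference conditions: 10%-scale nerves,
    mid-temporal injury, calibrated defaults.

    Session-scoped because it is by far the most expensive fixture; the
    steady-state outcome tests and the size-selectivity property all read
    from it.  Five seeds keep the full suite inside a desk-scale budget.
    """
    return repeat_study(StudyConfig(), seeds=list(range(5)))
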