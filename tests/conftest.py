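import numpy as np
import pytest

from scbam.core import make_grid_montage
from scbam.synthgen import SimSpec, simulate_run, simulate_session


@pytest.fixture(scope="session")
def small_montage():
    """6 x 6 grid at the real inter-electrode pitch."""
    return make_grid_montage(6, 6, 8.6)


@pytest.fixture(scope="session")
def tiny_montage():
    return make_grid_montage(4, 4, 8.6)


@pytest.fixture(scope="session")
def small_run(tiny_montage):
    """One short run with a clear class effect: (SimSpec, Recording, events)."""
    spec = SimSpec(n_runs=1, trials_per_run=10, seed=42, effect_size=1.5)
    rec, events = simulate_run(spec, tiny_montage, 0)
    return spec, rec, events


@pytest.fixture(scope="session")
def separable_session(small_montage):
    """Five short runs with a strong class effect for pipeline tests."""
    spec = SimSpec(n_runs=5, trials_per_run=15, seed=7, effect_size=2.0)
    return spec, simulate_session(spec, small_montage)
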