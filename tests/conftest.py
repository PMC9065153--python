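import numpy as np
import pytest

from screptime import (WindowGrid, make_timing_profile,
                       simulate_deterministic_cells, simulate_g1_cells)


@pytest.fixture(scope="session")
def small_grid() -> WindowGrid:
    return WindowGrid.fixed_windows({"chr1": 2000 * 20_000,
                                     "chr2": 1000 * 20_000})


@pytest.fixture(scope="session")
def timing_profile():
    return make_timing_profile(5000, 75, seed=101)


@pytest.fixture(scope="session")
def det_cells(timing_profile):
    """A reusable batch of deterministic-program S-phase cells."""
    return simulate_deterministic_cells(timing_profile, 60, seed=102)


@pytest.fixture(scope="session")
def g1_cells(timing_profile):
    return simulate_g1_cells(timing_profile.grid, 60, seed=103)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
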