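import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from granupbm import (GranuleEnsemble, MaterialSet, ProcessConditions,
                      SimulationConfig, VolumeGrid, build_grid)


@pytest.fixture
def materials():
    return MaterialSet()


@pytest.fixture
def process():
    return ProcessConditions()


@pytest.fixture
def grid():
    return build_grid(31.5e-6, 6000e-6, 12)


@pytest.fixture
def empty_ensemble(grid):
    return GranuleEnsemble(grid=grid)


def put(ensemble, i, j, k, n, le=0.0, li=0.0):
    """Place n granules in cell (i, j, k) with per-particle liquid."""
    ensemble.F[i, j, k] += n
    ensemble.Le[i, j, k] += n * le
    ensemble.Li[i, j, k] += n * li
    return ensemble


@pytest.fixture
def micro_config():
    """A seconds-scale configuration for integration tests.

    Small charge and fast spray so the full two-phase run finishes in
    well under a second of simulated 6 s on a coarse grid.
    """
    return SimulationConfig().replace(
        process={"charge_mass": 0.05, "q_spray": 1.0e-5, "t_end": 6.0},
        numerics={"n_bins": 8, "record_interval": 2.0},
    )
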