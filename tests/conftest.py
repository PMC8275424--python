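import numpy as np
import pytest

import brainunit as bu


@pytest.fixture(scope="session")
def defaults() -> bu.ModelParameters:
    return bu.default_parameters()


@pytest.fixture(scope="session")
def small_grid_overrides() -> dict:
    """Desk-scale-reduced grid for fast unit tests."""
    return {"grid": {"n_x": 7, "n_y": 7, "n_z": 7, "n_edge": 7,
                     "dt": 0.05, "t_end": 2.0, "snapshot_times": (2.0,)}}


@pytest.fixture(scope="session")
def preset_runs() -> dict[str, bu.SimulationResult]:
    """All nine reference scenarios, run once at the default desk scale."""
    return {s.name: bu.run_simulation(s) for s in bu.preset_scenarios()}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
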