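import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_grid():
    """Full default condition grid on the coarse charge grid, fixed seed.

    4 survival levels x 2 height profiles x 2 IPGs, stimulating contact #6,
    recording at the 11 other contacts; shared by the slower end-to-end
    checks so the simulation runs once per session.
    """
    from ecapsim.experiments import ExperimentConfig, run_grid

    grid = run_grid(ExperimentConfig(seed=1))
    assert not grid.failures, grid.failures
    return grid


@pytest.fixture(scope="session")
def grid_tables(default_grid):
    from ecapsim.experiments import (
        normalized_max_amplitudes,
        summarize_ipg_effects,
        summarize_thresholds_slopes,
    )

    return {
        "thresholds_slopes": summarize_thresholds_slopes(default_grid),
        "ipg_effects": summarize_ipg_effects(default_grid),
        "normalized_max": normalized_max_amplitudes(default_grid),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
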