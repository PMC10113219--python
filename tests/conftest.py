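import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import conngrad as cg

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort config used across tests: fast but non-trivial."""
    return cg.SimulationConfig(
        n_controls=8,
        n_patients=8,
        n_timepoints=60,
        n_outside_voxels=120,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cg.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = cg.SimulationConfig(
        n_controls=3,
        n_patients=3,
        n_timepoints=60,
        n_outside_voxels=120,
        noise_sd=0.0,
        seed=5,
    )
    return cg.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mapped_small_cohort(small_cohort):
    """Modes + coordinates for every subject of the small cohort."""
    from conngrad.pipeline import map_subject

    out = []
    coords = None
    for img in small_cohort.images:
        modes, coords = map_subject(
            img,
            small_cohort.roi_mask,
            small_cohort.brain_mask,
            small_cohort.affine,
            n_modes=2,
        )
        out.append(modes)
    return out, coords
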