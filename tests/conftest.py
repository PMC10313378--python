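import numpy as np
import pandas as pd
import pytest

from frcscape.io import default_panel
from frcscape.synthetic import (
    CohortConfig,
    NetworkParams,
    default_tfe_archetypes,
    generate_cohort,
    generate_frc_network,
    generate_sample_image,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel(1.0)


@pytest.fixture(scope="session")
def archetypes():
    return {a.name: a for a in default_tfe_archetypes()}


@pytest.fixture(scope="session")
def network_fixture():
    """density-2 fiber network on 512x512 @ 1 um/px with its ground truth."""
    params = NetworkParams(field_size_px=(512, 512), pixel_size_um=1.0,
                           fiber_density=2.0, seed=3)
    raster, truth = generate_frc_network(params)
    return params, raster, truth


@pytest.fixture(scope="session")
def coupled_sample(archetypes):
    """A rendered core with coupled CD8 placement (TFE4-like)."""
    net = NetworkParams(field_size_px=(256, 256), pixel_size_um=1.0, seed=5)
    return generate_sample_image(net, archetypes["TFE4"], 200, seed=11)


@pytest.fixture(scope="session")
def uncoupled_sample(archetypes):
    """A rendered core with uncoupled CD8 placement, clearance 12 um."""
    net = NetworkParams(field_size_px=(256, 256), pixel_size_um=1.0, seed=5)
    return generate_sample_image(net, archetypes["TFE1"], 100, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """16-sample, 1-core cohort used by the recovery tests."""
    cfg = CohortConfig(
        n_samples=16,
        cores_per_sample=1,
        n_cd8_per_core=80,
        core_field_px=(128, 128),
        mixing_noise_sd=0.05,
        seed=2,
    )
    return generate_cohort(cfg)
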