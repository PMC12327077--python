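"""Shared fixtures: one small simulated subject reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from rulefmri.design import Condition, generate_subject
from rulefmri.lss import estimate_all_trials
from rulefmri.pipeline import central_region_mask, simulate_subject
from rulefmri.simulate import NoiseConfig, RegionEffectSpec, default_geometry


@pytest.fixture(scope="session")
def small_design():
    """One 6-block (single-run) analyzable design with populated behavior."""
    return generate_subject("sub-01", seed=11, n_blocks=6)


@pytest.fixture(scope="session")
def geometry10():
    return default_geometry((10, 10, 10), voxel_size=3.0)


@pytest.fixture(scope="session")
def region(geometry10):
    return central_region_mask(geometry10, radius_voxels=2)


@pytest.fixture(scope="session")
def effect_spec(region):
    return RegionEffectSpec(
        name="region",
        region_mask=region,
        identity_snr=0.5,
        cross_stage_consistency=0.6,
        trend_slope_by_condition={c: -0.15 for c in Condition},
    )


@pytest.fixture(scope="session")
def sim_subject(geometry10, effect_spec):
    """One simulated 6-block subject with planted effects (seed 11)."""
    return simulate_subject(
        "sub-01", seed=11, n_blocks=6, geometry=geometry10,
        specs=[effect_spec], noise=NoiseConfig(),
    )


@pytest.fixture(scope="session")
def tps(sim_subject, region):
    """Region-restricted LSS trial patterns for the simulated subject."""
    return estimate_all_trials(sim_subject.bolds, sim_subject.design, mask=region)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
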