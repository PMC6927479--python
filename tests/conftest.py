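import numpy as np
import pytest

from connet import simulate

SMALL_SIZES = {
    "Default": 10,
    "DorsalAttn": 8,
    "Visual": 8,
    "FrontoParietal": 7,
    "SomatomotorHand": 7,
}


def small_config(n_participants=200, seed=0, **overrides):
    """A 40-parcel, 5-network configuration for fast simulations."""
    kw = dict(
        n_parcels=40,
        network_sizes=dict(SMALL_SIZES),
        within_block_mean={k: 0.5 for k in SMALL_SIZES},
        between_block_special={("Default", "DorsalAttn"): -0.15},
        planted_pairs=[("Default", "DorsalAttn", -0.2)],
        n_participants=n_participants,
        n_sites=8,
        master_seed=seed,
    )
    kw.update(overrides)
    return simulate.SimConfig(**kw)


@pytest.fixture(scope="session")
def cohort400():
    """Shared 400-participant cohort with planted effects."""
    return simulate.simulate_cohort(small_config(n_participants=400, seed=11))


@pytest.fixture(scope="session")
def quiet_cohort():
    """Cohort with no manufacturer bias or extra scanner noise: uniform
    participant SD, useful for variability and null checks."""
    cfg = small_config(
        n_participants=500, seed=7,
        manufacturer_bias_intercept=0.0, manufacturer_bias_slope=0.0,
        manufacturer_noise_scale={}, planted_pairs=[],
        missing_behavior_fraction=0.0)
    return simulate.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
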