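import numpy as np
import pytest

from fecundity.config import MCMCControls, RunConfig
from fecundity.simulate import GenerativeParams, StandConfig, simulate_world


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_world():
    """A modest single-species stand with traps and crop counts."""
    cfg = StandConfig(n_trees=20, n_years=10, extent_m=60)
    par = GenerativeParams(
        beta_rho=(-2.0, 0.1),
        beta_psi={"intercept": 6.5, "diameter_cm": 0.03},
        tau_ind=0.3,
        tau_yr=0.4,
        sigma=0.4,
        kernel_scale=80.0,
    )
    return simulate_world(
        cfg, par, 42, n_traps=5, crop_fraction=0.5, crop_observation_prob=0.5
    )


@pytest.fixture(scope="session")
def quick_fit(small_world):
    """A short two-chain fit of the small world, for structural checks
    (not for statistical assertions)."""
    import fecundity as fc

    rc = RunConfig(
        mcmc=MCMCControls(iterations=120, burn_in=60, chains=2),
        kernel_scale_m2=80.0,
    )
    return fc.fit(
        small_world.trees,
        small_world.covariates,
        small_world.traps,
        small_world.crop_counts,
        rc,
        design_columns=["intercept", "diameter_cm"],
        rng=7,
    )
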