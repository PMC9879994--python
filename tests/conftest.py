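import dataclasses

import numpy as np
import pytest

from reefmass.simulate import SpeciesSimConfig, generate_specimens


@pytest.fixture(scope="session")
def recovery_cfg() -> SpeciesSimConfig:
    """Generating parameters used throughout the recovery tests:
    a power law with a=0.3, b=2.7 and 20% multiplicative noise over a
    realistic mid-size diameter range."""
    return SpeciesSimConfig(
        species="Catalaphyllia jardinei", true_a=0.3, true_b=2.7, sigma_log=0.2,
        diameter_log_mean=1.97, diameter_log_sd=0.31,
        diameter_min_cm=3.9, diameter_max_cm=13.4,
    )


@pytest.fixture(scope="session")
def make_dataset(recovery_cfg):
    """Factory: (n, seed, noise, **cfg overrides) -> (records, x, y, cfg)."""

    def _make(n=300, seed=0, noise="lognormal", **overrides):
        cfg = dataclasses.replace(recovery_cfg, **overrides) if overrides else recovery_cfg
        recs = generate_specimens(cfg, n, seed=seed, noise=noise)
        x = np.array([r.max_diameter_cm for r in recs])
        y = np.array([r.weight_g for r in recs])
        return recs, x, y, cfg

    return _make


@pytest.fixture(scope="session")
def fitted_lognormal(make_dataset):
    """One shared lognormal-likelihood fit (n=300, seeded) reused by tests
    that only need plausible posterior draws."""
    from reefmass import SizeWeightRegressor

    recs, x, y, cfg = make_dataset(n=300, seed=42)
    reg = SizeWeightRegressor(likelihood="lognormal", n_iter=4000, random_state=1)
    reg.fit(x, y)
    return reg, recs
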