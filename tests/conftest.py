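import logging

import numpy as np
import pytest

import cestpipe as cp
from cestpipe.phantom import FieldSpec, default_tissue_pools

logging.getLogger("cestpipe").setLevel(logging.ERROR)


def small_config(**overrides) -> cp.PhantomConfig:
    """24x24x6 phantom with fields spanning their nominal ranges."""
    extent = 24 * 1.85
    kwargs = dict(
        grid_shape=(24, 24, 6),
        noise_sigma=0.0,
        seed=7,
        b0_field=FieldSpec(mean=0.0, amplitude=0.3, wavelength_mm=1.5 * extent),
        b1_field=FieldSpec(mean=1.0, amplitude=0.15, wavelength_mm=extent),
    )
    kwargs.update(overrides)
    return cp.PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless two-power phantom with varying B0/B1 (shared, read-only)."""
    return cp.generate_phantom(small_config())


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_phantom):
    """Normalised + water-fitted 2.3 µT series of the shared phantom."""
    ds = noiseless_phantom
    zs = cp.normalise(ds.series[2.3], ds.brain_mask)
    fits = cp.fit_water_lorentzian_volume(zs)
    return ds, zs, fits


@pytest.fixture(scope="session")
def flat_field_phantom():
    """Noiseless phantom with flat B0/B1, no MT pool (clean LD oracle)."""
    cfg = small_config(
        b0_field=FieldSpec(mean=0.0, amplitude=0.0),
        b1_field=FieldSpec(mean=1.0, amplitude=0.0),
        tissue_pools=default_tissue_pools(include_mt=False),
    )
    return cp.generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)
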