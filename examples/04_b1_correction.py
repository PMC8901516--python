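"""Show what contrast-based B1 correction buys on an inhomogeneous field.

A phantom with relative B1 spanning [0.85, 1.15] makes the uncorrected
LD_amide maps spatially heterogeneous even in uniform tissue; interpolating
each voxel's contrast across its effective powers (with a zero-power
anchor) and evaluating at 3.8 uT removes most of that variation.
"""

import numpy as np

import cestpipe as cp
from cestpipe.contrasts import contrasts_at_power
from cestpipe.phantom import FieldSpec, default_tissue_pools
from cestpipe.pipeline import process_cest
from cestpipe.zspectrum import b0_correct, fit_water_lorentzian_volume, normalise

extent = 24 * 1.85
config = cp.PhantomConfig(
    grid_shape=(24, 24, 4), noise_sigma=0.0, seed=5,
    b0_field=FieldSpec(mean=0.0, amplitude=0.0),
    b1_field=FieldSpec(mean=1.0, amplitude=0.15, wavelength_mm=extent),
    tissue_pools=default_tissue_pools(include_mt=False),
)
ds = cp.generate_phantom(config)
corrected = process_cest(ds.series, ds.b1_map, ds.brain_mask)["LDamide"]

uncorrected = {}
for p, series in ds.series.items():
    zs = normalise(series, ds.brain_mask)
    fits = fit_water_lorentzian_volume(zs)
    zc = b0_correct(zs, fits)
    refit = fit_water_lorentzian_volume(zc, center_bounds=(-0.2, 0.2))
    uncorrected[p] = contrasts_at_power(zc, refit, p)["LDamide"]

sel = (corrected[3.8].valid_mask & uncorrected[2.3].valid_mask
       & uncorrected[4.0].valid_mask & (ds.truth.tissue_labels == 1))
cv = lambda v: np.std(v) / abs(np.mean(v))
print(f"coefficient of variation of LD_amide over homogeneous tissue:")
print(f"  uncorrected 2.3 uT: {cv(uncorrected[2.3].values[sel]):.4f}")
print(f"  uncorrected 4.0 uT: {cv(uncorrected[4.0].values[sel]):.4f}")
print(f"  corrected to 3.8 uT: {cv(corrected[3.8].values[sel]):.4f}")
# The corrected map's CV should be several times smaller: residual spatial
# variation no longer tracks the transmit-field pattern.
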