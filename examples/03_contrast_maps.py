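"""Compute B0/B1-corrected MTR_asym, LD_amide and LD_NOE maps.

Runs the full pipeline on a noiseless phantom and reports ROI means at the
two target powers (2.5 and 3.8 uT).  LD_amide separates the amide signal
that MTR_asym partially cancels against NOE, so the tumour-NAWM contrast
is cleaner in LD_amide.
"""

import cestpipe as cp
from cestpipe.pipeline import process_cest
from cestpipe.roi import roi_means

config = cp.PhantomConfig(grid_shape=(24, 24, 6), noise_sigma=0.0, seed=1)
ds = cp.generate_phantom(config)
corrected = process_cest(ds.series, ds.b1_map, ds.brain_mask)

for name in ("MTRasym", "LDamide", "LDnoe"):
    for power, cmap in sorted(corrected[name].items()):
        stats = roi_means(cmap, ds.rois)
        print(f"{name:8s} @ {power:.1f} uT: "
              f"tumour {stats.loc['tumour', 'mean']:+.4f} +- {stats.loc['tumour', 'sd']:.4f}, "
              f"NAWM {stats.loc['nawm', 'mean']:+.4f} +- {stats.loc['nawm', 'sd']:.4f}")
# Expected pattern: LD_amide and LD_NOE positive with tumour > NAWM for
# LD_amide; MTR_asym negative in NAWM (NOE outweighs amide there).
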