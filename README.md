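# cestpipe

Analysis pipeline for pulsed 3D CEST (chemical exchange saturation
transfer) MRI of non-enhancing glioma, from raw 4D offset-resolved volumes
to B0/B1-corrected amide-weighted contrast maps and per-patient
tumour-heterogeneity metrics. A multi-pool synthetic phantom generator with
known ground truth makes every stage testable without patient data.

## Who this is for

Researchers processing 3 T pulsed-CEST brain acquisitions in which two
Z-spectrum series (nominal saturation powers 2.3 and 4.0 µT, 31 offsets
between +6 and −6 ppm, two unsaturated M0 references) are used to map amide
proton transfer (APT, +3.5 ppm) and nuclear Overhauser enhancement (NOE,
−3.5 ppm) effects, and to quantify how much of a T2-FLAIR-delineated tumour
shows hyperintense amide-weighted signal relative to contralateral
normal-appearing white matter (NAWM).

## The model

Per voxel, the normalised Z-spectrum is `Z(Δω) = S(Δω) / M0`. A
four-parameter Lorentzian is fitted on the restricted window
`|Δω| ≥ 6 ppm ∪ |Δω| ≤ 1.75 ppm` (13 of the 31 offsets), which excludes the
amide, NOE and mid-offset region:

    Z(Δω) = c − A·(Γ/2)² / ((Γ/2)² + (Δω − δ0)²)

The fitted centre δ0 estimates the local B0 offset; B0 correction
re-evaluates the measured spectrum at `Δω + δ0` (shape-preserving PCHIP),
putting the water minimum at 0 ppm. From the corrected spectra:

* `MTR_asym = Z(−3.5) − Z(+3.5)` — the classic asymmetry, conflating amide
  and NOE;
* `LD_amide = L_fit(+3.5) − Z(+3.5)` and `LD_noe = L_fit(−3.5) − Z(−3.5)`
  — Lorentzian differences against the refitted water line, separating the
  two pools.

Contrast-based B1 correction interpolates each voxel's contrast across its
effective powers `{0, 2.3·b1_rel, 4.0·b1_rel}` (zero saturation ⇒ zero
contrast anchors the curve) and evaluates at 2.5 and 3.8 µT — below the
nominal powers, so low-B1 voxels are interpolated rather than extrapolated.

Heterogeneity is quantified with the NAWM-derived threshold

    S_thresh = mean_NAWM + 2·sd_NAWM

(voxelwise statistics over the patient's own NAWM ROI); the percentage of
tumour voxels strictly above it is reported per slice and for the whole
tumour, with cohort roll-ups (mean, sample SD, min–max, Cohen's d).

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_contrast_maps.py` (noiseless 24×24×6 phantom,
default tissue parameters) prints:

```
MTRasym  @ 2.5 uT: tumour -0.0004 +- 0.0000, NAWM -0.0047 +- 0.0001
MTRasym  @ 3.8 uT: tumour -0.0005 +- 0.0000, NAWM -0.0073 +- 0.0002
LDamide  @ 2.5 uT: tumour +0.0170 +- 0.0001, NAWM +0.0112 +- 0.0003
LDamide  @ 3.8 uT: tumour +0.0252 +- 0.0002, NAWM +0.0167 +- 0.0002
LDnoe    @ 2.5 uT: tumour +0.0175 +- 0.0001, NAWM +0.0158 +- 0.0001
LDnoe    @ 3.8 uT: tumour +0.0258 +- 0.0002, NAWM +0.0239 +- 0.0000
```

NAWM MTR_asym is negative (the NOE dip outweighs the amide dip in healthy
white matter), both LD contrasts are positive, and the tumour's elevated
amide pool shows up as LD_amide tumour > NAWM at both powers — the
separation MTR_asym partially cancels away. `examples/05_heterogeneity_report.py`
then thresholds a noisy phantom tumour against its NAWM (threshold 0.0279 =
0.0164 + 2×0.0058) and finds 20.0% of the tumour volume hyperintense, next
to the bundled 18-patient cohort summary (17.9% ± 13.3%, min–max
2.4%–54.5%).

A thin CLI wraps the same pipeline for shell use:

```sh
cestpipe simulate phantom.yaml --out sim/
cestpipe run-all run.yaml
```

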