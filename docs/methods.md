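# Methods

## Scope

`cestpipe` implements the analysis side of a steady-state pulsed CEST
protocol at 3 T: Z-spectrum normalisation, water-line Lorentzian fitting,
B0 correction by spectrum shifting, MTR asymmetry and Lorentzian-difference
(LD) contrasts, contrast-based B1 correction, and NAWM-referenced
tumour-heterogeneity statistics. Acquisition physics (pulse sequences,
spoiled-GRE signal equations, fat suppression), motion correction and
registration, tissue segmentation and tumour delineation, B1-map estimation
from raw data, multi-pool Lorentzian decomposition, and mixed-effects
group regression are all out of scope; masks, the relative-B1 map and the
offset schedule are inputs.

## Forward model of the synthetic phantom

The phantom generates Z-spectra as a sum of Lorentzian saturation lines,

    Z(Δω) = 1 − Σᵢ Aᵢ(P)·(Γᵢ/2)² / ((Γᵢ/2)² + (Δω − δᵢ − δ_B0)²),

deliberately the same family the analysis fits, so ground truth is analytic
and every downstream estimate has an exact oracle. It is not a
Bloch–McConnell integration: exchange kinetics, relaxation and
pulsed-saturation duty-cycle effects are collapsed into each pool's
amplitude. Saturation-power dependence uses a rational curve

    Aᵢ(P) = Aᵢ,ref · s(P)/s(P_ref),   s(P) = P²/(P² + k²),

monotone in P and exactly zero at P = 0 — consistent with the zero-power
anchor the B1 correction relies on. The halfpoint k (µT) sets how fast a
pool grows with B1. Reference power: 2.3 µT (the lower nominal power).

Default pools were calibrated once so the NAWM LD values and their growth
from 2.5 to 3.8 µT match what is typical of healthy white matter at 3 T
(LD_amide ≈ 0.012→0.018, LD_NOE ≈ 0.017→0.025); that growth ratio (≈1.5×)
back-solves to k ≈ 3 µT for the amide and NOE pools:

| pool  | centre (ppm) | Γ (ppm) | A_ref NAWM | A_ref tumour | k (µT) |
|-------|--------------|---------|------------|--------------|--------|
| water | 0            | 2.0     | 0.80       | 0.80         | 1.0    |
| amide | +3.5         | 1.5     | 0.012      | 0.018        | 3.0    |
| NOE   | −3.5         | 3.0     | 0.017      | 0.019        | 3.0    |
| MT    | 0            | 50      | 0.06       | 0.05         | 1.5    |

The broad MT pool saturates early with B1 (semisolid) and is mildly reduced
in tumour. Its width/amplitude were chosen so that, after the water-fit
baseline absorbs most of it, the residual background leaves the end-to-end
NAWM LD values on the scales above; a steeper MT growth (halfpoint ≥2.5 µT)
inflates NAWM LD by ~40% and erodes the tumour–NAWM contrast, which is why
the earlier-saturating parameterisation was adopted.

Geometry: an elliptic-cylinder "brain" through all slices, an ellipsoidal
tumour with elevated amide amplitude, and a contralateral NAWM reference
ROI obtained by mirroring the tumour ellipsoid in x. B0 (ppm) and relative
B1 fields are smooth low-frequency sinusoids with configurable amplitude
and wavelength, evaluated on grid-centred coordinates so they actually
swing through ± their amplitude; defaults (±0.3 ppm, 0.85–1.15 relative B1)
are configurable assumptions of plausible 3 T inhomogeneity, not measured
facts. Noise is additive Gaussian on the raw images (sd = noise_sigma·M0,
default 1% — the high-SNR limit of Rician magnitude noise), applied to the
CEST images and to both M0 acquisitions so normalisation noise propagation
is exercised. Default grid 64×64×12 voxels of 1.85×1.85×5 mm, mirroring a
12-slice whole-tumour acquisition.

What passing phantom tests does *not* show about real data: no motion, no
registration error, no Rician floor at low SNR, no exchange-rate or
relaxation variation, no partial-volume mixing at ROI boundaries, no
asymmetric MT line, and tumours that are internally homogeneous unless
constructed otherwise.

## Offset schedule

The standard schedule has 31 offsets — 15 symmetric pairs (±6.0, ±5.5,
±5.0, ±4.5, ±4.0, ±3.75, ±3.5, ±3.0, ±2.5, ±2.0, ±1.5, ±1.0, ±0.75, ±0.5,
±0.25) plus 0 ppm — densely sampling the water line (for B0 estimation) and
the ±3.5 ppm evaluation offsets; with the two unsaturated M0 images a
session totals 33 images. The saturation duty cycle is 20 ms per 35.4 ms TR
(56.5%). The schedule lives in a JSON/text sidecar whose order is
authoritative end-to-end; readers accept any schedule whose length matches
the 4D series, and all window selections are predicates on ppm values, not
indices.

## Water-line fit and B0 correction

Fit window: `|Δω| ≥ 6 ∪ |Δω| ≤ 1.75` ppm (13 points of the standard
schedule), excluding the CEST pools. The model has a free constant baseline
c ∈ [0.8, 1.2] — in vivo the spectrum does not return to 1 at ±6 ppm, and c
absorbs the MT background; remaining bounds A ∈ [0, 1.2], Γ ∈ [0.3, 10]
ppm, δ0 ∈ [−1.5, 1.5] ppm keep the fit identifiable. Optimisation is
bounded trust-region least squares with an analytic Jacobian; initial
values come from the data (baseline from the window maximum, centre from
the core argmin). Degenerate voxels (fewer than 5 usable window points,
optimiser failure) are marked non-converged rather than raised; a flat
spectrum converges to A ≈ 0 with an unidentifiable centre.

The B0 estimate is the fitted centre (the analytic minimum of the fit) —
exact and noise-robust compared with a grid argmin. Correction evaluates
the measured spectrum at `Δω + δ0` with a monotone shape-preserving PCHIP
interpolant (cubic splines overshoot at the sharp water dip; linear is a
configurable fallback), so the corrected value at 0 ppm is the water
minimum. The direction convention is pinned by a symmetry oracle in the
tests, so the sign cannot silently flip. Voxels with |δ0| > 1 ppm are
dropped by default (configurable to keep-with-warning).

Shift targets that overshoot the measured range by ≤ 0.5 ppm are evaluated
at the spectrum edge rather than invalidated: the spectrum is nearly flat
at ±6 ppm (clamp error ~7×10⁻⁴), whereas losing a wing point from the
refit window moves the fitted baseline enough to shift LD systematically
by ~10%. Larger overshoots invalidate the offset for that voxel, and a
zero tolerance restores strict invalidation.

After correction the water line is refitted with the centre bounded to
±0.2 ppm; LD uses this refit. With the centre pinned exactly to 0 the
identity `MTR_asym = LD_amide − LD_NOE` holds to machine precision (the
fitted line is then symmetric); with the free bounded centre it holds to
~2×10⁻⁴ on the phantom.

## LD estimator bias and the B1-correction oracle

LD is not an unbiased estimate of the pool amplitude: the amide/NOE tails
that reach into the fit window depress the fitted baseline, making LD a
roughly proportional underestimate (~30% with the default pool set). This
is inherent to the published estimator, not a defect; comparisons between
tissues and powers share the bias. Consequently the ground truth used for
B1-correction accuracy is the *contrast-versus-power curve of the estimator
itself*: clean spectra are simulated per tissue at unit relative B1 across
powers and passed through the same fit+difference path
(`phantom.reference_ld_curve`). That curve never sees the phantom's B1
field or the correction step, so it is an independent oracle for what a
perfectly corrected map should converge to.

B1 correction interpolates per voxel over support points
`{(0,0), (2.3·b1, C₁), (4.0·b1, C₂)}`, piecewise linear by default — three
points cannot support a stable spline; PCHIP is optional. Targets 2.5 and
3.8 µT sit below the nominals so voxels with reduced B1 interpolate;
a target beyond a voxel's largest support power is masked by default
(clamping to the curve end is the configurable alternative). Coincident or
non-positive support powers mask the voxel.

## Thresholding and group statistics

σ_NAWM is the voxelwise sample SD within the patient's own NAWM ROI on the
corrected map — at the reported scales (NAWM mean ≈ 0.018, threshold ≈
0.031) the implied σ ≈ 0.0065 is an order of magnitude above across-patient
variability, so a voxel-scale statistic is the only consistent reading.
Hyperintensity uses a strict `>`; thresholds need ≥10 valid NAWM voxels.
Per-slice percentages are relative to that slice's tumour voxels (a
whole-tumour-relative column is also emitted); slice 1 is the most proximal
slice (first index along the third image axis). Group summaries use the
sample SD (n−1), which reproduces the bundled cohort's printed 13.3 from
its 18 percentages. Cohen's d uses the independent-groups pooled-SD formula
`(mean_T − mean_N)/√((s_T² + s_N²)/2)` on per-patient ROI means; the
variant is named in the output because rounded published summaries cannot
pin it down exactly.

## Problem sizes and numerical defaults

Voxelwise fitting costs ~1 ms/voxel, so the shipped tests and the
acceptance script scale the phantoms to the question being asked: B0
recovery runs the full 64×64×12 grid (~30 k brain voxels, ≈25 s); the
B1-correction property uses 32×32×6 with a flat B0 field — B0-shift edge
effects perturb LD by ~2×10⁻³, which would drown the B1 signal being
measured, and B0 handling is validated separately; identity and unit tests
use 24×24×6 and smaller. Threshold calibration uses 20 000 synthetic
Gaussian NAWM voxels and a constructed tumour with exactly 20% of voxels
elevated far above the cut. All randomness flows from explicit seeds; the
acceptance script derives every phantom seed from its `--seed` argument.

## Known limitations

* Single-Lorentzian water fit only; amine (2–3 ppm) and asymmetric MT
  contributions fold into the contrasts, as in the underlying method.
* B0 estimation uses the CEST data itself; hydroxyl resonances near
  0.9 ppm can bias it at high saturation power (the window's 1.75 ppm core
  bound limits but does not eliminate this).
* With two measured powers the contrast-versus-power interpolant is a
  chord; curvature between 2.3·b1 and 4.0·b1 leaves a small residual error
  (~2×10⁻³ relative CV on the phantom) after correction.
* The per-voxel fitting loop is plain Python over scipy's optimiser;
  whole-brain 128×128×12 data will take minutes per series on one core.
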