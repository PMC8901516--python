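"""Constants of the steady-state pulsed CEST protocol this pipeline targets.

A 3D spoiled-gradient-echo read-out interleaves a short Gaussian saturation
pulse with every excitation, sampling 31 saturation offsets between +6 and
-6 ppm at two nominal saturation powers, plus two unsaturated reference
(M0) images.  All offsets are in ppm relative to the water resonance;
saturation powers are RMS B1 amplitudes in microtesla.
"""

from __future__ import annotations

import numpy as np

# 31-offset schedule in acquisition order (downfield to upfield): 15
# symmetric pairs plus the on-resonance point, sampling densely around the
# water line (B0 estimation) and around the ±3.5 ppm evaluation offsets.
STANDARD_OFFSETS_PPM: tuple[float, ...] = (
    6.0, 5.5, 5.0, 4.5, 4.0, 3.75, 3.5, 3.0, 2.5, 2.0, 1.5,
    1.0, 0.75, 0.5, 0.25, 0.0, -0.25, -0.5, -0.75, -1.0, -1.5,
    -2.0, -2.5, -3.0, -3.5, -3.75, -4.0, -4.5, -5.0, -5.5, -6.0,
)
assert len(STANDARD_OFFSETS_PPM) == 31

#: Nominal saturation powers of the two acquired series (µT, RMS).
SATURATION_POWERS_UT: tuple[float, float] = (2.3, 4.0)

#: Evaluation powers for contrast-based B1 correction (µT).  Chosen below
#: the nominal powers so that voxels with locally reduced B1 are still
#: interpolated, never extrapolated.
TARGET_POWERS_UT: tuple[float, float] = (2.5, 3.8)

#: Number of unsaturated reference images acquired per session.
N_M0_IMAGES: int = 2

#: Saturation pulse duration and repetition time (ms).
SATURATION_PULSE_MS: float = 20.0
TR_MS: float = 35.4

#: Default voxel spacing of the CEST grid (mm).
VOXEL_SIZE_MM: tuple[float, float, float] = (1.85, 1.85, 5.0)

#: Amide (+3.5 ppm) and relayed-NOE (-3.5 ppm) evaluation offsets.
AMIDE_PPM: float = 3.5
NOE_PPM: float = -3.5


def n_images_total() -> int:
    """Total images per saturation power: offsets plus M0 references."""
    return len(STANDARD_OFFSETS_PPM) + N_M0_IMAGES


def duty_cycle() -> float:
    """Saturation duty cycle (fraction of TR spent saturating)."""
    return SATURATION_PULSE_MS / TR_MS


def validate_offsets(offsets_ppm: np.ndarray) -> np.ndarray:
    """Validate and return an offset schedule as a float array.

    Raises ``ValueError`` on non-finite entries or duplicates; order is
    preserved (the sidecar order is authoritative end-to-end).
    """
    offsets = np.asarray(offsets_ppm, dtype=float).ravel()
    if offsets.size == 0:
        raise ValueError("offset schedule is empty")
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offset schedule contains non-finite values")
    if np.unique(offsets).size != offsets.size:
        raise ValueError("offset schedule contains duplicate offsets")
    return offsets
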