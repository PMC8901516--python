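"""Contrast-based B1 correction.

The two CEST series are acquired at nominal powers of 2.3 and 4.0 µT, but
the local transmit field scales the power each voxel actually experiences.
Given a relative-B1 map, each voxel's measured contrasts sit at effective
powers ``P_nom · b1_rel``; together with an artificial anchor at zero power
(no saturation ⇒ no CEST contrast) they define a per-voxel contrast-versus-
power curve.  Evaluating that curve at common target powers — 2.5 and
3.8 µT by default, chosen below the nominal powers so that voxels with
reduced B1 are interpolated rather than extrapolated — yields maps at a
uniform effective power.

With only two measured powers plus the zero anchor the default interpolant
is piecewise linear; a shape-preserving PCHIP is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import acquisition
from .contrasts import ContrastMap


@dataclass(frozen=True)
class B1CorrectionConfig:
    nominal_powers_uT: tuple[float, ...] = acquisition.SATURATION_POWERS_UT
    target_powers_uT: tuple[float, ...] = acquisition.TARGET_POWERS_UT
    interpolation: str = "linear"  # or "pchip"
    extrapolation_policy: str = "mask"  # or "clamp"

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.nominal_powers_uT):
            raise ValueError("nominal powers must be positive")
        if any(p <= 0 for p in self.target_powers_uT):
            raise ValueError("target powers must be positive")
        if self.interpolation not in ("linear", "pchip"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.extrapolation_policy not in ("mask", "clamp"):
            raise ValueError(f"unknown extrapolation policy {self.extrapolation_policy!r}")


def b1_correct_contrast(
    maps_per_power: dict[float, ContrastMap],
    b1_rel: np.ndarray,
    config: B1CorrectionConfig = B1CorrectionConfig(),
) -> dict[float, ContrastMap]:
    """Correct one contrast to the configured target powers.

    ``maps_per_power`` holds the uncorrected maps keyed by nominal power;
    all must share grid and contrast name.  Per voxel the support points
    ``{(0, 0)} ∪ {(P_nom · b1_rel, C)}`` are interpolated in effective
    power.  Voxels where a target power exceeds the largest support power
    are masked (default) or clamped to the curve end; voxels with
    non-positive B1 or coincident support powers are masked.
    """
    nominals = list(config.nominal_powers_uT)
    if sorted(maps_per_power) != sorted(nominals):
        raise ValueError(
            f"maps_per_power keys {sorted(maps_per_power)} do not match "
            f"configured nominal powers {sorted(nominals)}"
        )
    maps = [maps_per_power[p] for p in nominals]
    names = {m.contrast_name for m in maps}
    if len(names) != 1:
        raise ValueError(f"mixed contrast names {names}")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1 or maps[0].values.shape != np.asarray(b1_rel).shape:
        raise ValueError("contrast maps and B1 map must share one grid")
    name = maps[0].contrast_name

    b1 = np.asarray(b1_rel, dtype=float)
    base_mask = np.logical_and.reduce([m.valid_mask for m in maps]) & (b1 > 0)
    targets = list(config.target_powers_uT)

    out_vals = {t: np.full(b1.shape, np.nan) for t in targets}
    out_mask = {t: np.zeros(b1.shape, dtype=bool) for t in targets}

    values = np.stack([m.values for m in maps], axis=-1)  # (..., n_nominal)
    for idx in np.argwhere(base_mask):
        i, j, k = idx
        powers = np.array([0.0] + [p * b1[i, j, k] for p in nominals])
        cvals = np.concatenate([[0.0], values[i, j, k]])
        order = np.argsort(powers)
        powers, cvals = powers[order], cvals[order]
        if np.any(np.diff(powers) < 1e-9):
            continue  # degenerate support: masked
        pmax = powers[-1]
        for t in targets:
            if t > pmax + 1e-12:
                if config.extrapolation_policy == "mask":
                    continue
                tt = pmax
            else:
                tt = t
            if config.interpolation == "linear":
                v = float(np.interp(tt, powers, cvals))
            else:
                v = float(PchipInterpolator(powers, cvals)(tt))
            out_vals[t][i, j, k] = v
            out_mask[t][i, j, k] = True

    return {
        t: ContrastMap(values=out_vals[t], contrast_name=name, power_uT=float(t),
                       mask=out_mask[t])
        for t in targets
    }
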