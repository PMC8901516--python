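"""Synthetic multi-pool CEST phantom with known ground truth.

The forward model is a sum of Lorentzian saturation lines — water, amide
(+3.5 ppm), relayed NOE (-3.5 ppm) and a broad symmetric MT pool — which is
exactly the family the analysis fits, so every downstream stage can be
checked against analytic truth.  Saturation-power dependence of each pool
amplitude follows a rational saturation curve A(P) ∝ P²/(P² + k²), which is
monotone in P and zero at P = 0, consistent with the artificial zero-power
anchor used by the contrast-based B1 correction.

Spatial realism is limited to what the analysis is sensitive to: smooth
sinusoidal B0 (ppm) and relative-B1 fields, an ellipsoidal tumour with
elevated amide amplitude inside an elliptic-cylinder "brain", a mirrored
contralateral NAWM reference region, and additive Gaussian noise on the raw
images (high-SNR limit of Rician magnitude noise), including the M0 images
so normalisation noise propagation is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import acquisition
from .io import CESTSeries, ROISet

#: Reference saturation power at which pool amplitudes are specified (µT).
REFERENCE_POWER_UT: float = 2.3


@dataclass(frozen=True)
class PoolSpec:
    """One saturable proton pool.

    Parameters
    ----------
    name
        Pool label (``"water"``, ``"amide"``, ``"noe"``, ``"mt"`` ...).
    center_ppm
        Chemical shift of the pool relative to water.
    fwhm_ppm
        Full width at half maximum of the Lorentzian line.
    amplitude_at_ref
        Peak fractional saturation (0–1) at ``REFERENCE_POWER_UT``.
    b1_halfpoint_uT
        Saturation power at which the amplitude reaches half its
        asymptotic value; controls how the pool grows with B1.
    """

    name: str
    center_ppm: float
    fwhm_ppm: float
    amplitude_at_ref: float
    b1_halfpoint_uT: float

    def __post_init__(self) -> None:
        if self.fwhm_ppm <= 0:
            raise ValueError(f"pool {self.name!r}: fwhm_ppm must be > 0")
        if not 0.0 <= self.amplitude_at_ref < 1.0:
            raise ValueError(f"pool {self.name!r}: amplitude_at_ref must be in [0, 1)")
        if self.b1_halfpoint_uT <= 0:
            raise ValueError(f"pool {self.name!r}: b1_halfpoint_uT must be > 0")

    def amplitude(self, sat_power_uT, ref_power_uT: float = REFERENCE_POWER_UT):
        """Peak amplitude at saturation power ``sat_power_uT`` (µT).

        Rational saturation curve ``A(P) = A_ref · s(P)/s(P_ref)`` with
        ``s(P) = P²/(P² + k²)``; vectorised over ``sat_power_uT``.
        """
        p2 = np.square(np.asarray(sat_power_uT, dtype=float))
        k2 = self.b1_halfpoint_uT**2
        ref = ref_power_uT**2 / (ref_power_uT**2 + k2)
        return self.amplitude_at_ref * (p2 / (p2 + k2)) / ref


def lorentzian_line(offsets_ppm, center_ppm, fwhm_ppm):
    """Unit-amplitude Lorentzian ``(Γ/2)² / ((Γ/2)² + (Δω − δ)²)``."""
    hw2 = (fwhm_ppm / 2.0) ** 2
    return hw2 / (hw2 + np.square(np.asarray(offsets_ppm, dtype=float) - center_ppm))


def simulate_zspectrum(
    pools,
    offsets_ppm,
    b0_shift_ppm: float = 0.0,
    sat_power_uT: float = REFERENCE_POWER_UT,
    ref_power_uT: float = REFERENCE_POWER_UT,
):
    """Noiseless Z-spectrum of a pool set at one saturation power.

    ``Z(Δω) = 1 − Σ_i A_i(P) · (Γ_i/2)² / ((Γ_i/2)² + (Δω − δ_i − δ_B0)²)``

    where each pool's centre is displaced by the local B0 offset
    ``b0_shift_ppm`` and the amplitudes follow each pool's rational
    saturation curve.  At zero power the spectrum is identically one.
    """
    offsets = np.asarray(offsets_ppm, dtype=float)
    if offsets.size == 0:
        raise ValueError("offsets_ppm must be nonempty")
    if sat_power_uT < 0:
        raise ValueError("sat_power_uT must be >= 0")
    z = np.ones_like(offsets)
    for pool in pools:
        amp = pool.amplitude(sat_power_uT, ref_power_uT)
        z = z - amp * lorentzian_line(offsets, pool.center_ppm + b0_shift_ppm, pool.fwhm_ppm)
    return np.clip(z, 0.0, 1.0)


def default_tissue_pools(include_mt: bool = True) -> dict[str, list[PoolSpec]]:
    """Default pool parameters per tissue class at 3 T.

    Amide and NOE amplitudes are set so that the NAWM Lorentzian-difference
    values and their growth between 2.5 and 3.8 µT land in the range typical
    of healthy white matter at 3 T (LD_amide ≈ 0.012→0.018, LD_NOE ≈
    0.017→0.025), which back-solves to a B1 halfpoint near 3 µT; the tumour
    carries a 1.5× elevated amide amplitude (mobile-protein excess) and
    mildly elevated NOE.  The MT pool is broad, symmetric about water,
    saturates early with B1 (semisolid pool) and is mildly reduced in the
    tumour; most of it is absorbed by the water-fit baseline, the remainder
    adds the realistic background both LD contrasts ride on.
    """
    water = PoolSpec("water", 0.0, 2.0, 0.80, 1.0)
    mt_nawm = PoolSpec("mt", 0.0, 50.0, 0.06, 1.5)
    mt_tum = PoolSpec("mt", 0.0, 50.0, 0.05, 1.5)
    pools = {
        "nawm": [
            water,
            PoolSpec("amide", acquisition.AMIDE_PPM, 1.5, 0.012, 3.0),
            PoolSpec("noe", acquisition.NOE_PPM, 3.0, 0.017, 3.0),
        ],
        "tumour": [
            water,
            PoolSpec("amide", acquisition.AMIDE_PPM, 1.5, 0.018, 3.0),
            PoolSpec("noe", acquisition.NOE_PPM, 3.0, 0.019, 3.0),
        ],
    }
    if include_mt:
        pools["nawm"].append(mt_nawm)
        pools["tumour"].append(mt_tum)
    return pools


@dataclass(frozen=True)
class FieldSpec:
    """Smooth sinusoidal scalar field: ``mean + amplitude·sin(kx x)·cos(ky y)·cos(kz z)``."""

    mean: float = 0.0
    amplitude: float = 0.0
    wavelength_mm: float = 120.0

    def evaluate(self, grid_shape, voxel_size_mm) -> np.ndarray:
        # coordinates centred on the grid so the field swings both ways
        nx, ny, nz = grid_shape
        x = (np.arange(nx) - 0.5 * (nx - 1))[:, None, None] * voxel_size_mm[0]
        y = (np.arange(ny) - 0.5 * (ny - 1))[None, :, None] * voxel_size_mm[1]
        z = (np.arange(nz) - 0.5 * (nz - 1))[None, None, :] * voxel_size_mm[2]
        k = 2.0 * np.pi / self.wavelength_mm
        return self.mean + self.amplitude * np.sin(k * x) * np.cos(k * y) * np.cos(0.5 * k * z)


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid in voxel coordinates."""

    center_vox: tuple[float, float, float]
    radii_vox: tuple[float, float, float]

    def mask(self, grid_shape) -> np.ndarray:
        cx, cy, cz = self.center_vox
        rx, ry, rz = self.radii_vox
        nx, ny, nz = grid_shape
        x = np.arange(nx)[:, None, None]
        y = np.arange(ny)[None, :, None]
        z = np.arange(nz)[None, None, :]
        d2 = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
        return d2 <= 1.0

    def within(self, grid_shape) -> bool:
        return all(
            c - r >= -0.5 and c + r <= n - 0.5
            for c, r, n in zip(self.center_vox, self.radii_vox, grid_shape)
        )


def _default_tumour(grid_shape) -> EllipsoidSpec:
    nx, ny, nz = grid_shape
    return EllipsoidSpec(
        center_vox=(0.66 * nx, 0.5 * ny, 0.5 * (nz - 1)),
        radii_vox=(0.14 * nx, 0.14 * ny, 0.30 * nz),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one synthetic acquisition session."""

    grid_shape: tuple[int, int, int] = (64, 64, 12)
    voxel_size_mm: tuple[float, float, float] = acquisition.VOXEL_SIZE_MM
    offsets_ppm: tuple[float, ...] = acquisition.STANDARD_OFFSETS_PPM
    sat_powers_uT: tuple[float, ...] = acquisition.SATURATION_POWERS_UT
    ref_power_uT: float = REFERENCE_POWER_UT
    tissue_pools: dict[str, list[PoolSpec]] = field(default_factory=default_tissue_pools)
    tumour_geometry: EllipsoidSpec | None = None  # None -> default for grid
    b0_field: FieldSpec = FieldSpec(mean=0.0, amplitude=0.3, wavelength_mm=150.0)
    b1_field: FieldSpec = FieldSpec(mean=1.0, amplitude=0.15, wavelength_mm=200.0)
    noise_sigma: float = 0.01  # sd relative to M0
    m0_value: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        offsets = acquisition.validate_offsets(np.array(self.offsets_ppm))
        if 0.0 not in offsets:
            raise ValueError("offset schedule must contain 0 ppm")
        if len(self.sat_powers_uT) == 0:
            raise ValueError("sat_powers_uT must be nonempty")
        if any(p <= 0 for p in self.sat_powers_uT):
            raise ValueError("saturation powers must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for tissue in ("nawm", "tumour"):
            if tissue not in self.tissue_pools:
                raise ValueError(f"tissue_pools must define {tissue!r}")

    def tumour(self) -> EllipsoidSpec:
        return self.tumour_geometry or _default_tumour(self.grid_shape)

    def with_(self, **kw) -> "PhantomConfig":
        return replace(self, **kw)


# tissue label codes in GroundTruth.tissue_labels
BACKGROUND, NAWM_LABEL, TUMOUR_LABEL = 0, 1, 2


@dataclass
class GroundTruth:
    """Voxelwise truth for parameter-recovery tests."""

    b0_map_ppm: np.ndarray
    b1_map_rel: np.ndarray
    pool_amplitude_maps: dict[str, np.ndarray]  # amplitude at ref power
    tissue_labels: np.ndarray  # 0 background, 1 brain/NAWM, 2 tumour

    def pool_for(self, tissue: str, name: str, config: PhantomConfig) -> PoolSpec:
        for pool in config.tissue_pools[tissue]:
            if pool.name == name:
                return pool
        raise KeyError(f"no pool {name!r} in tissue {tissue!r}")


@dataclass
class PhantomDataset:
    """Everything :func:`generate_phantom` produces, in memory."""

    config: PhantomConfig
    series: dict[float, CESTSeries]  # keyed by nominal power (µT)
    m0_pair: np.ndarray  # 4D, the two unsaturated acquisitions
    b1_map: np.ndarray
    rois: ROISet
    brain_mask: np.ndarray
    truth: GroundTruth


def _brain_mask(grid_shape) -> np.ndarray:
    nx, ny, nz = grid_shape
    return EllipsoidSpec(
        center_vox=(0.5 * (nx - 1), 0.5 * (ny - 1), 0.5 * (nz - 1)),
        radii_vox=(0.44 * nx, 0.44 * ny, 10 * nz),  # elliptic cylinder through all slices
    ).mask(grid_shape)


def generate_phantom(config: PhantomConfig) -> PhantomDataset:
    """Generate a full two-power synthetic CEST session.

    Deterministic given ``config.seed``: one ``numpy`` Generator drives all
    noise draws in a fixed order.  Raw images are ``M0 · Z`` plus Gaussian
    noise of sd ``noise_sigma · m0_value``, added independently per image
    (including the two M0 acquisitions).
    """
    shape = config.grid_shape
    tumour = config.tumour()
    if not tumour.within(shape):
        raise ValueError("tumour geometry extends outside the grid")

    brain = _brain_mask(shape)
    tumour_mask = tumour.mask(shape) & brain
    if tumour_mask.sum() == 0:
        raise ValueError("tumour geometry contains no brain voxels")
    # contralateral reference region: the tumour ellipsoid mirrored in x
    cx, cy, cz = tumour.center_vox
    nawm_geom = EllipsoidSpec((shape[0] - 1 - cx, cy, cz), tumour.radii_vox)
    nawm_mask = nawm_geom.mask(shape) & brain & ~tumour_mask

    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = NAWM_LABEL
    labels[tumour_mask] = TUMOUR_LABEL

    b0_map = config.b0_field.evaluate(shape, config.voxel_size_mm)
    b1_map = config.b1_field.evaluate(shape, config.voxel_size_mm)

    offsets = np.asarray(config.offsets_ppm, dtype=float)
    n_off = offsets.size

    pool_names = sorted({p.name for t in ("nawm", "tumour") for p in config.tissue_pools[t]})
    amp_maps = {name: np.zeros(shape) for name in pool_names}
    for tissue, label in (("nawm", NAWM_LABEL), ("tumour", TUMOUR_LABEL)):
        sel = labels == label
        for pool in config.tissue_pools[tissue]:
            amp_maps[pool.name][sel] = pool.amplitude_at_ref

    rng = np.random.default_rng(config.seed)
    sigma = config.noise_sigma * config.m0_value
    m0_map = np.where(brain, config.m0_value, 0.0)

    series: dict[float, CESTSeries] = {}
    for power in config.sat_powers_uT:
        z = _forward_volume(config, offsets, labels, b0_map, b1_map, power)
        volumes = m0_map[..., None] * z
        if sigma > 0:
            volumes = volumes + rng.normal(0.0, sigma, size=volumes.shape)
        series[power] = CESTSeries(
            volumes=volumes,
            offsets_ppm=offsets,
            m0=m0_map.copy(),  # replaced below once the noisy M0 pair exists
            nominal_power_uT=power,
            voxel_size_mm=config.voxel_size_mm,
        )

    m0_pair = np.repeat(m0_map[..., None], acquisition.N_M0_IMAGES, axis=3)
    if sigma > 0:
        m0_pair = m0_pair + rng.normal(0.0, sigma, size=m0_pair.shape)
    m0_mean = m0_pair.mean(axis=3)
    for s in series.values():
        s.m0 = m0_mean

    truth = GroundTruth(
        b0_map_ppm=b0_map,
        b1_map_rel=b1_map,
        pool_amplitude_maps=amp_maps,
        tissue_labels=labels,
    )
    rois = ROISet(tumour_mask=tumour_mask, nawm_mask=nawm_mask)
    return PhantomDataset(
        config=config,
        series=series,
        m0_pair=m0_pair,
        b1_map=b1_map,
        rois=rois,
        brain_mask=brain,
        truth=truth,
    )


def _forward_volume(config, offsets, labels, b0_map, b1_map, nominal_power):
    """Noiseless Z-spectra for every brain voxel at one nominal power."""
    shape = labels.shape
    z = np.ones(shape + (offsets.size,))
    for tissue, label in (("nawm", NAWM_LABEL), ("tumour", TUMOUR_LABEL)):
        sel = labels == label
        if not sel.any():
            continue
        b0 = b0_map[sel]  # (n,)
        p_eff = nominal_power * b1_map[sel]  # local effective power
        zv = np.ones((b0.size, offsets.size))
        for pool in config.tissue_pools[tissue]:
            amp = pool.amplitude(p_eff, config.ref_power_uT)[:, None]
            u = offsets[None, :] - pool.center_ppm - b0[:, None]
            hw2 = (pool.fwhm_ppm / 2.0) ** 2
            zv -= amp * (hw2 / (hw2 + u * u))
        z[sel] = np.clip(zv, 0.0, 1.0)
    return z


def true_ld_curve(config: PhantomConfig, tissue: str, pool_name: str, powers_uT):
    """Ground-truth pool amplitude (= the pool's Lorentzian peak depth) as a
    function of saturation power — the phantom's rational amplitude curve."""
    dummy = GroundTruth(None, None, {}, None)
    pool = dummy.pool_for(tissue, pool_name, config)
    return pool.amplitude(np.asarray(powers_uT, dtype=float), config.ref_power_uT)


def reference_ld_curve(config: PhantomConfig, tissue: str, at_ppm: float, powers_uT):
    """Ground-truth Lorentzian-difference value versus *effective* power.

    Simulates one clean spectrum per power (no noise, no B0 shift, unit
    relative B1) and runs the same water-fit + difference estimator the
    pipeline uses, so the curve carries the estimator's own systematic
    offset (pool tails inside the fit window depress the fitted baseline).
    This is the curve a perfectly B1-corrected map should land on; it never
    sees the phantom's B1 field, so it is independent of the correction
    under test.
    """
    from .contrasts import REFIT_CENTER_BOUND_PPM
    from .zspectrum import fit_water_lorentzian

    offsets = np.asarray(config.offsets_ppm, dtype=float)
    pools = config.tissue_pools[tissue]
    out = []
    for p in np.atleast_1d(np.asarray(powers_uT, dtype=float)):
        z = simulate_zspectrum(pools, offsets, 0.0, p, config.ref_power_uT)
        fit = fit_water_lorentzian(
            z, offsets,
            center_bounds=(-REFIT_CENTER_BOUND_PPM, REFIT_CENTER_BOUND_PPM),
        )
        k = int(np.flatnonzero(np.abs(offsets - at_ppm) < 1e-6)[0])
        out.append(float(fit.evaluate([at_ppm])[0] - z[k]))
    return np.array(out)
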