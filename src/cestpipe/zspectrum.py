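"""Z-spectrum normalisation, water-line Lorentzian fitting and B0 correction.

The water line is fitted per voxel with a four-parameter Lorentzian

    Z(Δω) = c − A · (Γ/2)² / ((Γ/2)² + (Δω − δ0)²)

on a restricted window — the |Δω| ≥ 6 ppm wings plus the |Δω| ≤ 1.75 ppm
core — that excludes the amide, NOE and mid-offset MT region so the fit
tracks direct water saturation only.  The fitted centre δ0 is the per-voxel
B0 offset estimate; B0 correction re-evaluates each measured spectrum at
the shifted positions (nominal offset + δ0) with a shape-preserving PCHIP
interpolant, moving the water minimum to 0 ppm while keeping the nominal
offset schedule.

The free baseline c absorbs the broad MT background (in vivo the spectrum
does not return to 1 at ±6 ppm); its bounds keep the fit identifiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .io import CESTSeries

logger = logging.getLogger(__name__)

# fit window predicates (ppm), applied to nominal offsets
WINDOW_OUTER_PPM = 6.0
WINDOW_INNER_PPM = 1.75

# parameter bounds: A, fwhm Γ (ppm), centre δ0 (ppm), baseline c
BOUNDS_LO = np.array([0.0, 0.3, -1.5, 0.8])
BOUNDS_HI = np.array([1.2, 10.0, 1.5, 1.2])


@dataclass
class ZSpectra:
    """Per-voxel normalised Z-spectra on a shared offset schedule.

    ``valid`` marks, per voxel and offset, whether the value is usable —
    after B0 correction, shift targets outside the measured range become
    invalid for that voxel.
    """

    z: np.ndarray  # 4D (x, y, z, offset)
    offsets_ppm: np.ndarray
    mask: np.ndarray  # 3D bool, processing mask
    b0_corrected: bool = False
    valid: np.ndarray | None = None  # 4D bool

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.z)
        assert self.z.shape[3] == np.asarray(self.offsets_ppm).size

    def copy(self) -> "ZSpectra":
        return ZSpectra(self.z.copy(), np.array(self.offsets_ppm), self.mask.copy(),
                        self.b0_corrected, self.valid.copy())


@dataclass
class LorentzianFit:
    """Fitted water-line parameters for a single voxel."""

    amplitude: float
    fwhm_ppm: float
    center_ppm: float
    baseline: float
    rss: float
    converged: bool

    def evaluate(self, offsets_ppm):
        """The fitted Lorentzian evaluated analytically."""
        return _model(
            np.array([self.amplitude, self.fwhm_ppm, self.center_ppm, self.baseline]),
            np.asarray(offsets_ppm, dtype=float),
        )


@dataclass
class FitMaps:
    """Voxelwise :class:`LorentzianFit` results as parameter volumes."""

    amplitude: np.ndarray
    fwhm_ppm: np.ndarray
    center_ppm: np.ndarray
    baseline: np.ndarray
    rss: np.ndarray
    converged: np.ndarray  # bool

    def at(self, idx) -> LorentzianFit:
        return LorentzianFit(
            float(self.amplitude[idx]), float(self.fwhm_ppm[idx]),
            float(self.center_ppm[idx]), float(self.baseline[idx]),
            float(self.rss[idx]), bool(self.converged[idx]),
        )

    def evaluate(self, offsets_ppm) -> np.ndarray:
        """Fitted Lorentzians evaluated at ``offsets_ppm`` for every voxel."""
        off = np.asarray(offsets_ppm, dtype=float)
        hw2 = (self.fwhm_ppm[..., None] / 2.0) ** 2
        u = off[None, None, None, :] - self.center_ppm[..., None]
        return self.baseline[..., None] - self.amplitude[..., None] * hw2 / (hw2 + u * u)


def normalise(series: CESTSeries, mask: np.ndarray | None = None) -> ZSpectra:
    """Divide each saturated image by the mean unsaturated (M0) image.

    Voxels with non-positive M0 inside the mask are dropped from the mask
    (counted in the log); an all-zero M0 inside the mask is a hard error.
    """
    if mask is None:
        mask = np.ones(series.grid_shape, dtype=bool)
    mask = mask.astype(bool)
    good_m0 = series.m0 > 0
    if mask.any() and not (mask & good_m0).any():
        raise ValueError("M0 is non-positive at every masked voxel; check the M0 input")
    dropped = int((mask & ~good_m0).sum())
    if dropped:
        logger.warning("normalise: dropped %d voxels with non-positive M0", dropped)
    mask = mask & good_m0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = series.volumes / series.m0[..., None]
    z[~mask] = np.nan
    return ZSpectra(z=z, offsets_ppm=series.offsets_ppm, mask=mask, b0_corrected=False)


def fit_window_mask(offsets_ppm, outer=WINDOW_OUTER_PPM, inner=WINDOW_INNER_PPM) -> np.ndarray:
    """Boolean selector of fit-window offsets: |Δω| ≥ outer or |Δω| ≤ inner.

    Implemented as predicates on ppm values (not indices) so alternative
    schedules work; a 1e-9 tolerance guards against float representation.
    """
    a = np.abs(np.asarray(offsets_ppm, dtype=float))
    return (a >= outer - 1e-9) | (a <= inner + 1e-9)


def _model(theta, x):
    a, g, d, c = theta
    hw2 = (g / 2.0) ** 2
    return c - a * hw2 / (hw2 + (x - d) ** 2)


def _residual(theta, x, y):
    return _model(theta, x) - y


def _jacobian(theta, x, y):
    a, g, d, c = theta
    w = g / 2.0
    u = x - d
    den = w * w + u * u
    ja = -(w * w) / den
    jg = -a * w * u * u / (den * den)  # d/dΓ = d/dw · 1/2, w = Γ/2
    jd = -2.0 * a * w * w * u / (den * den)
    jc = np.ones_like(x)
    return np.stack([ja, jg, jd, jc], axis=1)


def fit_water_lorentzian(
    zspec,
    offsets_ppm,
    center_bounds: tuple[float, float] = (-1.5, 1.5),
    pin_center: float | None = None,
) -> LorentzianFit:
    """Least-squares water-line fit on the restricted window of one spectrum.

    Non-finite window points (e.g. invalidated by B0 shifting) are dropped;
    fewer than 5 usable window points is rejected.  With ``pin_center`` the
    centre is held fixed and only (A, Γ, c) are free — used for the refit
    on B0-corrected spectra whose centre is known to be ≈ 0.  An optimiser
    failure returns ``converged=False`` rather than raising.
    """
    x = np.asarray(offsets_ppm, dtype=float)
    y = np.asarray(zspec, dtype=float)
    sel = fit_window_mask(x) & np.isfinite(y)
    x, y = x[sel], y[sel]
    if x.size < 5:
        raise ValueError(f"fit window holds only {x.size} usable points (need >= 5)")

    lo, hi = BOUNDS_LO.copy(), BOUNDS_HI.copy()
    lo[2], hi[2] = center_bounds
    c0 = float(np.clip(np.max(y), lo[3] + 1e-6, hi[3] - 1e-6))
    core = np.abs(x) <= WINDOW_INNER_PPM + 1e-9
    d0 = float(x[core][np.argmin(y[core])]) if core.any() else 0.0
    d0 = float(np.clip(d0, lo[2] + 1e-6, hi[2] - 1e-6))
    a0 = float(np.clip(c0 - np.min(y), 1e-4, hi[0] - 1e-6))
    theta0 = np.array([a0, 2.0, d0, c0])

    if pin_center is not None:
        d_fixed = float(pin_center)

        def res3(t):
            return _residual(np.array([t[0], t[1], d_fixed, t[2]]), x, y)

        def jac3(t):
            return _jacobian(np.array([t[0], t[1], d_fixed, t[2]]), x, y)[:, [0, 1, 3]]

        try:
            sol = least_squares(res3, theta0[[0, 1, 3]], jac=jac3,
                                bounds=(lo[[0, 1, 3]], hi[[0, 1, 3]]), method="trf")
        except Exception:
            return LorentzianFit(np.nan, np.nan, d_fixed, np.nan, np.nan, False)
        a, g, c = sol.x
        theta = np.array([a, g, d_fixed, c])
        ok = sol.success
    else:
        try:
            sol = least_squares(
                _residual, theta0, jac=_jacobian, args=(x, y), bounds=(lo, hi), method="trf"
            )
        except Exception:
            return LorentzianFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
        theta = sol.x
        ok = sol.success
    rss = float(np.sum(_residual(theta, x, y) ** 2))
    return LorentzianFit(
        amplitude=float(theta[0]), fwhm_ppm=float(theta[1]),
        center_ppm=float(theta[2]), baseline=float(theta[3]),
        rss=rss, converged=bool(ok),
    )


def fit_water_lorentzian_volume(
    zspectra: ZSpectra,
    center_bounds: tuple[float, float] = (-1.5, 1.5),
    pin_center: float | None = None,
) -> FitMaps:
    """Water-line fit at every masked voxel; non-fittable voxels are
    marked non-converged (NaN parameters), never raised."""
    shape = zspectra.mask.shape
    out = FitMaps(
        amplitude=np.full(shape, np.nan), fwhm_ppm=np.full(shape, np.nan),
        center_ppm=np.full(shape, np.nan), baseline=np.full(shape, np.nan),
        rss=np.full(shape, np.nan), converged=np.zeros(shape, dtype=bool),
    )
    offsets = np.asarray(zspectra.offsets_ppm, dtype=float)
    zz = np.where(zspectra.valid, zspectra.z, np.nan)
    for idx in np.argwhere(zspectra.mask):
        i, j, k = idx
        try:
            fit = fit_water_lorentzian(zz[i, j, k], offsets,
                                       center_bounds=center_bounds, pin_center=pin_center)
        except ValueError:
            continue
        out.amplitude[i, j, k] = fit.amplitude
        out.fwhm_ppm[i, j, k] = fit.fwhm_ppm
        out.center_ppm[i, j, k] = fit.center_ppm
        out.baseline[i, j, k] = fit.baseline
        out.rss[i, j, k] = fit.rss
        out.converged[i, j, k] = fit.converged
    return out


def b0_correct(
    zspectra: ZSpectra,
    fits: FitMaps,
    max_shift_ppm: float = 1.0,
    shift_policy: str = "drop",
    interpolation: str = "pchip",
    edge_tolerance_ppm: float = 0.5,
) -> ZSpectra:
    """Shift each voxel's spectrum so its water minimum sits at 0 ppm.

    The corrected value at nominal offset ω is the measured spectrum
    interpolated at ω + δ0, where δ0 is the fitted water-line centre (the
    analytic minimum of the fit).  Shift targets that overshoot the
    measured range by at most ``edge_tolerance_ppm`` are evaluated at the
    nearest measured offset — the spectrum is nearly flat at the ±6 ppm
    wings, and losing a wing point destabilises the refitted baseline far
    more than the clamp's bounded error; targets further out are marked
    invalid for that voxel (set the tolerance to 0 to invalidate any
    overshoot).  Voxels with a non-converged fit are dropped from the mask;
    voxels with |δ0| beyond ``max_shift_ppm`` follow ``shift_policy``
    ("drop" or "keep").
    """
    if shift_policy not in ("drop", "keep"):
        raise ValueError(f"unknown shift_policy {shift_policy!r}")
    if interpolation not in ("pchip", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    offsets = np.asarray(zspectra.offsets_ppm, dtype=float)
    order = np.argsort(offsets)
    asc = offsets[order]

    mask = zspectra.mask & fits.converged
    n_nonconv = int((zspectra.mask & ~fits.converged).sum())
    if n_nonconv:
        logger.warning("b0_correct: dropped %d voxels with non-converged fits", n_nonconv)
    big = mask & (np.abs(fits.center_ppm) > max_shift_ppm)
    n_big = int(big.sum())
    if n_big:
        logger.warning(
            "b0_correct: %d voxels with |delta0| > %.2f ppm (%s)",
            n_big, max_shift_ppm, "dropped" if shift_policy == "drop" else "kept",
        )
        if shift_policy == "drop":
            mask = mask & ~big

    z_out = np.full_like(zspectra.z, np.nan)
    valid = np.zeros(zspectra.z.shape, dtype=bool)
    zz = np.where(zspectra.valid, zspectra.z, np.nan)
    for idx in np.argwhere(mask):
        i, j, k = idx
        yv = zz[i, j, k][order]
        fin = np.isfinite(yv)
        if fin.sum() < 2:
            mask[i, j, k] = False
            continue
        xs, ys = asc[fin], yv[fin]
        target = offsets + fits.center_ppm[i, j, k]
        tol = edge_tolerance_ppm + 1e-12
        inside = (target >= xs[0] - tol) & (target <= xs[-1] + tol)
        t = np.clip(target, xs[0], xs[-1])
        if interpolation == "pchip":
            vals = PchipInterpolator(xs, ys)(t)
        else:
            vals = np.interp(t, xs, ys)
        z_out[i, j, k][inside] = vals[inside]
        valid[i, j, k] = inside
    return ZSpectra(z=z_out, offsets_ppm=offsets.copy(), mask=mask,
                    b0_corrected=True, valid=valid)
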