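"""Normalisation, water-line fitting and B0 correction."""

import numpy as np
import pytest

import cestpipe as cp
from cestpipe import acquisition
from cestpipe.zspectrum import (
    b0_correct,
    fit_water_lorentzian,
    fit_water_lorentzian_volume,
    fit_window_mask,
    normalise,
)

from conftest import small_config

OFFSETS = np.array(acquisition.STANDARD_OFFSETS_PPM)


def water_spectrum(offsets, a=0.8, g=2.0, d=0.0, c=1.0):
    return c - a * (g / 2) ** 2 / ((g / 2) ** 2 + (offsets - d) ** 2)


class TestNormalise:
    def test_volumes_equal_to_m0_give_unit_spectra(self):
        m0 = np.full((4, 4, 2), 500.0)
        series = cp.CESTSeries(
            volumes=np.repeat(m0[..., None], 5, axis=3),
            offsets_ppm=np.array([6.0, 3.5, 0.0, -3.5, -6.0]),
            m0=m0, nominal_power_uT=2.3,
        )
        zs = normalise(series)
        assert np.allclose(zs.z, 1.0)
        assert not zs.b0_corrected

    def test_matches_forward_model_on_noiseless_phantom(self, noiseless_phantom):
        ds = noiseless_phantom
        zs = normalise(ds.series[2.3], ds.brain_mask)
        idx = tuple(np.argwhere(ds.rois.nawm_mask)[0])
        expected = cp.simulate_zspectrum(
            ds.config.tissue_pools["nawm"],
            ds.config.offsets_ppm,
            b0_shift_ppm=ds.truth.b0_map_ppm[idx],
            sat_power_uT=2.3 * ds.truth.b1_map_rel[idx],
        )
        np.testing.assert_allclose(zs.z[idx], expected, atol=1e-12)

    def test_zero_m0_voxel_excluded_and_counted(self, caplog):
        m0 = np.full((4, 4, 2), 500.0)
        m0[0, 0, 0] = 0.0
        series = cp.CESTSeries(
            volumes=np.ones((4, 4, 2, 5)),
            offsets_ppm=np.array([6.0, 3.5, 0.0, -3.5, -6.0]),
            m0=m0, nominal_power_uT=2.3,
        )
        with caplog.at_level("WARNING", logger="cestpipe.zspectrum"):
            zs = normalise(series)
        assert not zs.mask[0, 0, 0]
        assert zs.mask.sum() == 31
        assert "dropped 1 voxels" in caplog.text

    def test_all_zero_m0_is_hard_error(self):
        series = cp.CESTSeries(
            volumes=np.ones((2, 2, 1, 5)),
            offsets_ppm=np.array([6.0, 3.5, 0.0, -3.5, -6.0]),
            m0=np.zeros((2, 2, 1)), nominal_power_uT=2.3,
        )
        with pytest.raises(ValueError, match="M0"):
            normalise(series)


class TestFitWindow:
    def test_standard_schedule_window_membership(self):
        # wings at +-6 plus the +-1.75 core: exactly these 13 offsets
        expected = {6.0, -6.0, 1.5, -1.5, 1.0, -1.0, 0.75, -0.75,
                    0.5, -0.5, 0.25, -0.25, 0.0}
        sel = fit_window_mask(OFFSETS)
        assert set(OFFSETS[sel]) == expected
        # CEST offsets are excluded
        assert 3.5 not in OFFSETS[sel] and -3.5 not in OFFSETS[sel]

    def test_window_is_a_ppm_predicate_not_an_index_set(self):
        alt = np.array([-7.0, -6.0, -1.75, 0.0, 1.75, 2.0, 6.0, 7.0])
        np.testing.assert_array_equal(
            fit_window_mask(alt),
            [True, True, True, True, True, False, True, True],
        )


class TestFitWaterLorentzian:
    def test_exact_recovery_from_model_data(self):
        y = water_spectrum(OFFSETS, a=0.8, g=2.0, d=0.3, c=1.0)
        fit = fit_water_lorentzian(y, OFFSETS)
        assert fit.converged
        assert abs(fit.amplitude - 0.8) <= 1e-4
        assert abs(fit.fwhm_ppm - 2.0) <= 1e-4
        assert abs(fit.center_ppm - 0.3) <= 1e-4
        assert abs(fit.baseline - 1.0) <= 1e-4
        assert fit.rss < 1e-10

    def test_flat_spectrum_degenerates_to_zero_amplitude(self):
        fit = fit_water_lorentzian(np.ones_like(OFFSETS), OFFSETS)
        assert fit.converged
        assert fit.amplitude <= 1e-6

    def test_too_few_window_points_rejected(self):
        x = np.array([0.0, 0.5, -0.5, 3.5])
        with pytest.raises(ValueError, match="need >= 5"):
            fit_water_lorentzian(np.ones(4), x)

    def test_cest_pools_leave_positive_residual_at_amide_offset(self, flat_field_phantom):
        ds = flat_field_phantom
        zs = normalise(ds.series[4.0], ds.brain_mask)
        idx = tuple(np.argwhere(ds.rois.tumour_mask)[0])
        fit = fit_water_lorentzian(zs.z[idx], OFFSETS)
        k = list(OFFSETS).index(3.5)
        assert fit.evaluate([3.5])[0] - zs.z[idx][k] > 0  # Z dips below the fit

    def test_pinned_center_fit(self):
        y = water_spectrum(OFFSETS, a=0.7, g=1.8, d=0.0, c=0.95)
        fit = fit_water_lorentzian(y, OFFSETS, pin_center=0.0)
        assert fit.center_ppm == 0.0
        assert abs(fit.amplitude - 0.7) <= 1e-4


class TestB0Correct:
    def test_zero_shift_is_identity_at_measured_offsets(self):
        z = np.tile(water_spectrum(OFFSETS, d=0.0), (2, 2, 1, 1))
        zs = cp.ZSpectra(z=z, offsets_ppm=OFFSETS, mask=np.ones((2, 2, 1), dtype=bool))
        fits = fit_water_lorentzian_volume(zs)
        zc = b0_correct(zs, fits)
        sel = zc.valid
        np.testing.assert_allclose(zc.z[sel], z[sel], atol=1e-9)

    def test_recovers_field_and_centres_minimum(self, noiseless_fit):
        ds, zs, fits = noiseless_fit
        err = np.abs(fits.center_ppm - ds.truth.b0_map_ppm)[zs.mask & fits.converged]
        assert err.max() <= 0.05
        zc = b0_correct(zs, fits)
        refit = fit_water_lorentzian_volume(zc, center_bounds=(-0.2, 0.2))
        centres = refit.center_ppm[zc.mask & refit.converged]
        assert np.abs(centres).max() <= 0.05

    def test_symmetric_spectrum_restored_after_shift(self):
        pools = [cp.PoolSpec("water", 0.0, 2.0, 0.8, 1.0),
                 cp.PoolSpec("amide", 3.5, 2.0, 0.03, 3.0),
                 cp.PoolSpec("noe", -3.5, 2.0, 0.03, 3.0)]
        z = cp.simulate_zspectrum(pools, OFFSETS, b0_shift_ppm=0.2, sat_power_uT=2.3)
        zs = cp.ZSpectra(z=z[None, None, None, :], offsets_ppm=OFFSETS,
                         mask=np.ones((1, 1, 1), dtype=bool))
        fits = fit_water_lorentzian_volume(zs)
        zc = b0_correct(zs, fits)
        kp = list(OFFSETS).index(3.5)
        km = list(OFFSETS).index(-3.5)
        assert zc.valid[0, 0, 0, kp] and zc.valid[0, 0, 0, km]
        assert abs(zc.z[0, 0, 0, kp] - zc.z[0, 0, 0, km]) <= 1e-3

    def test_out_of_range_targets_clamped_then_invalidated(self):
        z = water_spectrum(OFFSETS, d=0.4)
        zs = cp.ZSpectra(z=z[None, None, None, :], offsets_ppm=OFFSETS,
                         mask=np.ones((1, 1, 1), dtype=bool))
        fits = fit_water_lorentzian_volume(zs)
        k6 = list(OFFSETS).index(6.0)
        # small overshoot (6.4 ppm): evaluated at the flat spectrum edge
        zc = b0_correct(zs, fits)
        assert zc.valid[0, 0, 0, k6]
        assert zc.z[0, 0, 0, k6] == pytest.approx(z[k6], abs=1e-3)
        # zero tolerance restores strict invalidation
        strict = b0_correct(zs, fits, edge_tolerance_ppm=0.0)
        assert not strict.valid[0, 0, 0, k6]
        assert np.isnan(strict.z[0, 0, 0, k6])

    def test_large_shift_policy(self):
        z = water_spectrum(OFFSETS, d=1.2)
        zs = cp.ZSpectra(z=np.tile(z, (1, 1, 1, 1)), offsets_ppm=OFFSETS,
                         mask=np.ones((1, 1, 1), dtype=bool))
        fits = fit_water_lorentzian_volume(zs)
        dropped = b0_correct(zs, fits, max_shift_ppm=1.0, shift_policy="drop")
        assert not dropped.mask.any()
        kept = b0_correct(zs, fits, max_shift_ppm=1.0, shift_policy="keep")
        assert kept.mask.all()


class TestNoiseMonotonicity:
    def test_fit_rss_grows_with_noise(self):
        rss = []
        for sigma in (0.0, 0.01, 0.03):
            ds = cp.generate_phantom(small_config(
                grid_shape=(12, 12, 2), noise_sigma=sigma, seed=5))
            zs = normalise(ds.series[2.3], ds.brain_mask)
            fits = fit_water_lorentzian_volume(zs)
            sel = zs.mask & fits.converged
            rss.append(np.nanmean(fits.rss[sel]))
        assert rss[0] <= rss[1] <= rss[2]
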