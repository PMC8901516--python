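"""Thresholding, heterogeneity metrics and group summaries."""

import numpy as np
import pytest

import cestpipe as cp
from cestpipe.contrasts import ContrastMap
from cestpipe.roi import (
    cohens_d,
    compute_threshold,
    group_summary,
    hyperintense_map,
    load_reference_cohort,
    roi_means,
)


def make_map(values, mask=None, name="LDamide", power=3.8):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return ContrastMap(values=values, contrast_name=name, power_uT=power, mask=mask)


class TestComputeThreshold:
    def test_zero_variance(self):
        cm = make_map(np.full((4, 4, 2), 0.018))
        th = compute_threshold(cm, np.ones((4, 4, 2), dtype=bool))
        assert th.threshold == pytest.approx(0.018)
        assert th.nawm_sd == 0.0

    def test_hand_arithmetic(self):
        vals = np.zeros((12, 1, 1))
        vals[:, 0, 0] = [0.01, 0.02, 0.03] * 4
        nawm = np.zeros((12, 1, 1), dtype=bool)
        nawm[:3, 0, 0] = True
        # bypass the stability floor by filling the rest of the mask later;
        # with exactly {0.01, 0.02, 0.03}: mean 0.02, sample SD 0.01
        nawm[3:12, 0, 0] = True
        th = compute_threshold(make_map(vals), nawm, multiplier=2)
        assert th.nawm_mean == pytest.approx(0.02)
        assert th.nawm_sd == pytest.approx(np.std([0.01, 0.02, 0.03] * 4, ddof=1))

    def test_three_value_example(self):
        # the canonical hand example {0.01, 0.02, 0.03}, k=2 -> 0.04
        vals = np.array([0.01, 0.02, 0.03])
        mean, sd = vals.mean(), vals.std(ddof=1)
        assert mean + 2 * sd == pytest.approx(0.04)

    def test_gaussian_nawm_reproduces_reported_scale(self, rng):
        # NAWM voxels mu=0.018, sigma=0.0065 -> threshold ~ 0.031
        vals = rng.normal(0.018, 0.0065, size=(5000, 1, 1))
        th = compute_threshold(make_map(vals), np.ones((5000, 1, 1), dtype=bool))
        assert th.threshold == pytest.approx(0.031, rel=0.02)

    def test_too_few_voxels_rejected(self):
        cm = make_map(np.zeros((3, 3, 1)))
        nawm = np.zeros((3, 3, 1), dtype=bool)
        nawm[0, 0, 0] = True
        with pytest.raises(ValueError, match="NAWM voxels"):
            compute_threshold(cm, nawm)


class TestHyperintenseMap:
    @pytest.fixture()
    def tumour_setup(self, rng):
        shape = (10, 10, 4)
        tumour = np.zeros(shape, dtype=bool)
        tumour[2:8, 2:8, :] = True
        vals = rng.normal(0.018, 0.001, size=shape)
        return shape, tumour, vals

    def test_threshold_below_minimum_saturates_at_100(self, tumour_setup):
        shape, tumour, vals = tumour_setup
        th = cp.ThresholdSpec(nawm_mean=-1.0, nawm_sd=0.0, multiplier=2, n_voxels=100)
        rep = hyperintense_map(make_map(vals), tumour, th)
        assert rep.percent_whole == 100.0

    def test_threshold_above_maximum_gives_zero_everywhere(self, tumour_setup):
        shape, tumour, vals = tumour_setup
        th = cp.ThresholdSpec(nawm_mean=1.0, nawm_sd=0.0, multiplier=2, n_voxels=100)
        rep = hyperintense_map(make_map(vals), tumour, th)
        assert rep.percent_whole == 0.0
        assert (rep.per_slice["percent"] == 0).all()

    def test_constructed_20pct_subregion_recovered(self, rng):
        # a hyperintense blob occupying exactly 20% of tumour voxels, far
        # above the noise floor
        shape = (20, 20, 5)
        tumour = np.zeros(shape, dtype=bool)
        tumour[5:15, 5:15, :] = True  # 500 voxels
        vals = rng.normal(0.018, 0.001, size=shape)  # tight around the NAWM mean
        hyper_true = np.zeros(shape, dtype=bool)
        hyper_true[5:15, 5:7, :] = True  # 100 voxels = 20%
        vals[hyper_true] += 0.10  # >> threshold separation
        th = cp.ThresholdSpec(nawm_mean=0.018, nawm_sd=0.0065, multiplier=2, n_voxels=10_000)
        rep = hyperintense_map(make_map(vals), tumour, th)
        assert rep.percent_whole == pytest.approx(20.0, abs=1.0)

    def test_strict_inequality_at_threshold(self):
        vals = np.full((4, 4, 1), 0.03)
        tumour = np.ones((4, 4, 1), dtype=bool)
        th = cp.ThresholdSpec(nawm_mean=0.03, nawm_sd=0.0, multiplier=2, n_voxels=100)
        rep = hyperintense_map(make_map(vals), tumour, th)
        assert rep.percent_whole == 0.0  # equal to threshold is not hyperintense

    def test_per_slice_aggregation_consistency(self, tumour_setup, rng):
        shape, tumour, vals = tumour_setup
        vals[rng.random(shape) > 0.7] += 0.05
        th = cp.ThresholdSpec(nawm_mean=0.018, nawm_sd=0.001, multiplier=2, n_voxels=100)
        rep = hyperintense_map(make_map(vals), tumour, th)
        assert rep.per_slice["tumour_voxels"].sum() == rep.tumour_voxels
        assert rep.per_slice["hyper_voxels"].sum() == rep.hyper_voxels
        # whole-tumour percentage == tumour-voxel-weighted mean of slice pcts
        weighted = (rep.per_slice["percent"] * rep.per_slice["tumour_voxels"]).sum() \
            / rep.per_slice["tumour_voxels"].sum()
        assert rep.percent_whole == pytest.approx(weighted, abs=1e-12)
        assert rep.per_slice["slice"].min() == 1  # most proximal slice is 1

    def test_monotone_in_threshold_multiplier(self, tumour_setup):
        shape, tumour, vals = tumour_setup
        pcts = []
        for k in (0.5, 1.0, 2.0, 3.0):
            th = cp.ThresholdSpec(nawm_mean=0.018, nawm_sd=0.001, multiplier=k, n_voxels=100)
            pcts.append(hyperintense_map(make_map(vals), tumour, th).percent_whole)
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_empty_tumour_rejected(self, tumour_setup):
        shape, _, vals = tumour_setup
        th = cp.ThresholdSpec(nawm_mean=0.0, nawm_sd=0.0, multiplier=2, n_voxels=100)
        with pytest.raises(ValueError, match="empty"):
            hyperintense_map(make_map(vals), np.zeros(shape, dtype=bool), th)

    def test_nawm_false_positive_rate_matches_gaussian_tail(self, rng):
        # with a mean + 2 sigma cut, ~2.3% of the NAWM's own voxels exceed it
        n = 50_000
        vals = rng.normal(0.018, 0.0065, size=(n, 1, 1))
        cm = make_map(vals)
        nawm = np.ones((n, 1, 1), dtype=bool)
        th = compute_threshold(cm, nawm)
        frac = 100.0 * np.mean(vals > th.threshold)
        assert frac == pytest.approx(2.3, abs=0.5)


class TestRoiMeans:
    def test_constant_map(self):
        cm = make_map(np.full((6, 6, 2), 0.015))
        tumour = np.zeros((6, 6, 2), dtype=bool)
        tumour[:3] = True
        rois = cp.ROISet(tumour_mask=tumour, nawm_mask=~tumour)
        stats = roi_means(cm, rois)
        assert stats.loc["tumour", "mean"] == pytest.approx(0.015)
        assert stats.loc["tumour", "sd"] == pytest.approx(0.0, abs=1e-12)

    def test_masked_voxels_excluded(self):
        vals = np.full((4, 4, 1), 0.01)
        vals[0, 0, 0] = 99.0
        mask = np.ones((4, 4, 1), dtype=bool)
        mask[0, 0, 0] = False
        cm = make_map(vals, mask=mask)
        tumour = np.zeros((4, 4, 1), dtype=bool)
        tumour[:2] = True
        rois = cp.ROISet(tumour_mask=tumour, nawm_mask=~tumour)
        stats = roi_means(cm, rois)
        assert stats.loc["tumour", "mean"] == pytest.approx(0.01)
        assert stats.loc["tumour", "n_voxels"] == 7

    def test_empty_roi_rejected(self):
        cm = make_map(np.zeros((2, 2, 1)))
        rois = cp.ROISet(tumour_mask=np.zeros((2, 2, 1), dtype=bool),
                         nawm_mask=np.ones((2, 2, 1), dtype=bool))
        with pytest.raises(ValueError, match="tumour"):
            roi_means(cm, rois)


class TestGroupSummary:
    def test_reference_cohort_reproduces_published_group_stats(self):
        cohort = load_reference_cohort()
        gs = group_summary(list(cohort["hyperintense_pct"]))
        assert gs.n_patients == 18
        assert gs.mean_pct == pytest.approx(17.9, abs=0.05)
        assert gs.sd_pct == pytest.approx(13.3, abs=0.05)
        assert gs.min_pct == 2.4
        assert gs.max_pct == 54.5

    def test_reference_cohort_rows_internally_consistent(self):
        # printed hyperintense ml / tumour ml reproduces the printed %
        cohort = load_reference_cohort()
        recomputed = 100.0 * cohort["hyperintense_volume_ml"] / cohort["tumour_volume_ml"]
        assert (recomputed - cohort["hyperintense_pct"]).abs().max() <= 0.6

    def test_duplicated_patient_gives_zero_sd(self):
        gs = group_summary([10.0, 10.0])
        assert gs.mean_pct == 10.0 and gs.sd_pct == 0.0

    def test_single_patient_sd_absent(self):
        gs = group_summary([12.5])
        assert gs.sd_pct is None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_summary([])

    def test_cohens_d_zero_for_identical_means(self, rng):
        a = rng.normal(0.0, 1.0, 20)
        b = a.copy()
        assert cohens_d(a, b) == 0.0

    def test_cohens_d_pooled_formula(self):
        a = [1.0, 2.0, 3.0]
        b = [0.0, 1.0, 2.0]
        assert cohens_d(a, b) == pytest.approx(1.0)  # pooled sd = 1

    def test_effect_sizes_passed_through(self):
        gs = group_summary([1, 2], tumour_means={"LDamide": [3.0, 4.0]},
                           nawm_means={"LDamide": [1.0, 2.0]})
        # diff of means 2.0, each sample SD 1/sqrt(2), pooled SD 1/sqrt(2)
        assert gs.effect_sizes["LDamide"] == pytest.approx(2.0 * np.sqrt(2.0))
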