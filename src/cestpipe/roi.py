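"""ROI statistics, hyperintensity thresholding and group summaries.

The per-patient hyperintensity threshold for an amide-weighted contrast is
derived from the contralateral normal-appearing white matter (NAWM):

    S_thresh = mean_NAWM + k · sd_NAWM        (k = 2 by default)

with the mean and the *voxelwise* standard deviation taken over the
patient's own NAWM ROI on the B0/B1-corrected map.  Voxels of the tumour
ROI strictly above the threshold form the hyperintense mask; volume
percentages are reported per slice (slice 1 = most proximal, the first
index along the slice axis) and for the whole tumour.  Group roll-ups give
mean, sample SD (n−1), min–max of the per-patient whole-tumour
percentages, and Cohen's d effect sizes on per-patient ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .contrasts import ContrastMap
from .io import ROISet


@dataclass(frozen=True)
class ThresholdSpec:
    """NAWM-derived hyperintensity threshold for one contrast map."""

    nawm_mean: float
    nawm_sd: float
    multiplier: float
    n_voxels: int

    @property
    def threshold(self) -> float:
        return self.nawm_mean + self.multiplier * self.nawm_sd


@dataclass
class HeterogeneityReport:
    """Per-patient hyperintense-volume metrics for one contrast × power."""

    patient_id: str
    contrast_name: str
    power_uT: float
    threshold: ThresholdSpec
    hyper_mask: np.ndarray
    tumour_voxels: int
    hyper_voxels: int
    percent_whole: float
    per_slice: pd.DataFrame  # slice, tumour_voxels, hyper_voxels, percent, percent_of_whole
    voxel_volume_ml: float

    @property
    def tumour_volume_ml(self) -> float:
        return self.tumour_voxels * self.voxel_volume_ml

    @property
    def hyper_volume_ml(self) -> float:
        return self.hyper_voxels * self.voxel_volume_ml


@dataclass
class GroupSummary:
    """Cohort roll-up of whole-tumour hyperintense percentages."""

    per_patient: list[float]
    mean_pct: float
    sd_pct: float | None  # None for a single patient
    min_pct: float
    max_pct: float
    n_patients: int
    effect_sizes: dict[str, float]


def compute_threshold(cmap: ContrastMap, nawm_mask: np.ndarray, multiplier: float = 2.0) -> ThresholdSpec:
    """NAWM mean + multiplier × voxelwise sample SD on the valid map."""
    sel = cmap.valid_mask & np.asarray(nawm_mask, dtype=bool)
    n = int(sel.sum())
    if n < 10:
        raise ValueError(f"only {n} valid NAWM voxels (need >= 10 for a stable threshold)")
    vals = cmap.values[sel]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return ThresholdSpec(nawm_mean=float(np.mean(vals)), nawm_sd=sd,
                         multiplier=float(multiplier), n_voxels=n)


def hyperintense_map(
    cmap: ContrastMap,
    tumour_mask: np.ndarray,
    threshold: ThresholdSpec,
    patient_id: str = "",
    voxel_size_mm=(1.85, 1.85, 5.0),
    slice_axis: int = 2,
) -> HeterogeneityReport:
    """Threshold the tumour ROI and compute per-slice / whole-tumour percentages.

    Hyperintensity uses a strict ``>``.  Per-slice rows are emitted only
    for slices containing at least one tumour voxel; ``percent`` is
    relative to that slice's tumour voxels, ``percent_of_whole`` relative
    to the whole tumour.
    """
    tumour = np.asarray(tumour_mask, dtype=bool) & cmap.valid_mask
    n_tum = int(tumour.sum())
    if n_tum == 0:
        raise ValueError("tumour ROI is empty on the map's validity mask")
    hyper = tumour & (cmap.values > threshold.threshold)
    n_hyp = int(hyper.sum())

    axes = tuple(a for a in range(3) if a != slice_axis)
    tum_per_slice = tumour.sum(axis=axes)
    hyp_per_slice = hyper.sum(axis=axes)
    rows = []
    for z in range(tumour.shape[slice_axis]):
        if tum_per_slice[z] == 0:
            continue
        rows.append({
            "slice": z + 1,  # slice 1 = most proximal
            "tumour_voxels": int(tum_per_slice[z]),
            "hyper_voxels": int(hyp_per_slice[z]),
            "percent": 100.0 * hyp_per_slice[z] / tum_per_slice[z],
            "percent_of_whole": 100.0 * hyp_per_slice[z] / n_tum,
        })
    if not rows:
        raise ValueError("no slice contains tumour voxels")
    return HeterogeneityReport(
        patient_id=patient_id,
        contrast_name=cmap.contrast_name,
        power_uT=cmap.power_uT,
        threshold=threshold,
        hyper_mask=hyper,
        tumour_voxels=n_tum,
        hyper_voxels=n_hyp,
        percent_whole=100.0 * n_hyp / n_tum,
        per_slice=pd.DataFrame(rows),
        voxel_volume_ml=float(np.prod(voxel_size_mm)) / 1000.0,
    )


def roi_means(cmap: ContrastMap, rois: ROISet) -> pd.DataFrame:
    """Mean, sample SD and voxel count of the map over each ROI."""
    rows = []
    for name, mask in (("tumour", rois.tumour_mask), ("nawm", rois.nawm_mask)):
        sel = cmap.valid_mask & mask
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"ROI {name!r} is empty on the map's validity mask")
        vals = cmap.values[sel]
        rows.append({
            "roi": name,
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if n > 1 else 0.0,
            "n_voxels": n,
        })
    return pd.DataFrame(rows).set_index("roi")


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled-SD formula ``sqrt((s_a² + s_b²)/2)``.

    Applied to per-patient ROI means (equal-length paired lists); the
    variant is the independent-groups pooled SD, not a paired d.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size != b.size:
        raise ValueError("groups must be equal length (one entry per patient)")
    if a.size < 2:
        raise ValueError("need >= 2 patients for an effect size")
    pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0 if np.mean(a) == np.mean(b) else np.inf * np.sign(np.mean(a) - np.mean(b))
    return float((np.mean(a) - np.mean(b)) / pooled)


def group_summary(
    percents,
    tumour_means: dict[str, list] | None = None,
    nawm_means: dict[str, list] | None = None,
) -> GroupSummary:
    """Cohort statistics of whole-tumour hyperintense percentages.

    ``percents`` is a list of per-patient percentages or of
    :class:`HeterogeneityReport`; optional per-contrast mean lists yield
    Cohen's d tumour-vs-NAWM effect sizes.
    """
    vals = [p.percent_whole if isinstance(p, HeterogeneityReport) else float(p) for p in percents]
    if len(vals) == 0:
        raise ValueError("empty patient list")
    arr = np.asarray(vals, dtype=float)
    effect = {}
    if tumour_means and nawm_means:
        for name in tumour_means:
            effect[name] = cohens_d(tumour_means[name], nawm_means[name])
    return GroupSummary(
        per_patient=vals,
        mean_pct=float(arr.mean()),
        sd_pct=float(arr.std(ddof=1)) if arr.size > 1 else None,
        min_pct=float(arr.min()),
        max_pct=float(arr.max()),
        n_patients=int(arr.size),
        effect_sizes=effect,
    )


def load_reference_cohort() -> pd.DataFrame:
    """Published 18-patient non-enhancing glioma cohort summary.

    Per-patient tumour volume, hyperintense volume and hyperintense volume
    percentage (amide-weighted Lorentzian difference at 3.8 µT), as printed
    in the source study's patient table; used as a worked group-statistics
    input and as a consistency check on the volume-percentage arithmetic.
    """
    with resources.files("cestpipe.data").joinpath("glioma_cohort.csv").open() as fh:
        return pd.read_csv(fh)
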