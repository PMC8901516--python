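"""End-to-end orchestration: simulate → process → report.

``process_cest`` is the in-memory core — normalise, fit, B0-correct, refit,
compute the three contrasts at both acquired powers, and B1-correct each
contrast to the target powers.  The ``run_*`` functions wrap it with file
I/O, validation, provenance recording and QC outputs for the command-line
interface.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acquisition

_version = "0.1.0"
from .b1 import B1CorrectionConfig, b1_correct_contrast
from .contrasts import ContrastMap, contrasts_at_power
from .io import (
    CESTSeries,
    ROISet,
    ValidationError,
    load_b1_map,
    load_cest_series,
    load_mask,
    save_volume,
    write_offsets,
)
from .phantom import PhantomConfig, PhantomDataset, generate_phantom
from .roi import compute_threshold, group_summary, hyperintense_map, roi_means
from .zspectrum import b0_correct, fit_water_lorentzian_volume, normalise
from .contrasts import REFIT_CENTER_BOUND_PPM

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-level configuration for a processing run (YAML/JSON on disk)."""

    output_dir: str
    series_paths: dict[float, str] = dc_field(default_factory=dict)  # power -> 4D NIfTI
    offsets_path: str | None = None
    m0_path: str | None = None
    b1_map_path: str | None = None
    tumour_mask_path: str | None = None
    nawm_mask_path: str | None = None
    brain_mask_path: str | None = None
    patient_id: str = "patient"
    threshold_multiplier: float = 2.0
    b1_correction: B1CorrectionConfig = dc_field(default_factory=B1CorrectionConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        b1cfg = raw.pop("b1_correction", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "series_paths"})
        if "series_paths" in raw:
            cfg.series_paths = {float(k): v for k, v in raw["series_paths"].items()}
        if b1cfg:
            cfg.b1_correction = B1CorrectionConfig(
                nominal_powers_uT=tuple(b1cfg.get("nominal_powers_uT", acquisition.SATURATION_POWERS_UT)),
                target_powers_uT=tuple(b1cfg.get("target_powers_uT", acquisition.TARGET_POWERS_UT)),
                interpolation=b1cfg.get("interpolation", "linear"),
                extrapolation_policy=b1cfg.get("extrapolation_policy", "mask"),
            )
        return cfg


def process_cest(
    series_by_power: dict[float, CESTSeries],
    b1_rel: np.ndarray,
    mask: np.ndarray | None = None,
    b1_config: B1CorrectionConfig | None = None,
) -> dict[str, dict[float, ContrastMap]]:
    """Full contrast pipeline in memory.

    Returns ``{contrast_name: {target_power: ContrastMap}}`` with the three
    B0- and B1-corrected contrasts at each configured target power.
    """
    if b1_config is None:
        b1_config = B1CorrectionConfig(nominal_powers_uT=tuple(sorted(series_by_power)))
    uncorrected: dict[str, dict[float, ContrastMap]] = {}
    for power, series in sorted(series_by_power.items()):
        t0 = time.perf_counter()
        zs = normalise(series, mask)
        fits = fit_water_lorentzian_volume(zs)
        zc = b0_correct(zs, fits)
        refits = fit_water_lorentzian_volume(
            zc, center_bounds=(-REFIT_CENTER_BOUND_PPM, REFIT_CENTER_BOUND_PPM)
        )
        for name, cmap in contrasts_at_power(zc, refits, power).items():
            uncorrected.setdefault(name, {})[power] = cmap
        logger.info("processed %.1f uT series in %.1f s", power, time.perf_counter() - t0)
    corrected: dict[str, dict[float, ContrastMap]] = {}
    for name, maps in uncorrected.items():
        corrected[name] = b1_correct_contrast(maps, b1_rel, b1_config)
    return corrected


# ---------------------------------------------------------------------------
# disk-facing commands


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _provenance(outdir: Path, config_echo: dict, seed: int, timings: dict) -> None:
    record = {
        "software": {"name": "cestpipe", "version": _version},
        "seed": seed,
        "config": config_echo,
        "stage_timings_s": timings,
    }
    (outdir / "provenance.json").write_text(json.dumps(record, indent=2, default=str) + "\n")


def run_simulate(config: PhantomConfig, output_dir) -> dict:
    """Generate a phantom session and write every artefact plus a manifest."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    ds = generate_phantom(config)
    vox = config.voxel_size_mm
    files: dict[str, Path] = {}
    for power, series in ds.series.items():
        p = outdir / f"cest_{power:.1f}uT.nii.gz"
        save_volume(p, series.volumes, vox)
        files[f"series_{power:.1f}uT"] = p
    files["m0_pair"] = outdir / "m0_pair.nii.gz"
    save_volume(files["m0_pair"], ds.m0_pair, vox)
    files["b1_map"] = outdir / "b1_rel.nii.gz"
    save_volume(files["b1_map"], ds.b1_map, vox)
    files["tumour_mask"] = outdir / "tumour_mask.nii.gz"
    save_volume(files["tumour_mask"], ds.rois.tumour_mask.astype(np.uint8), vox)
    files["nawm_mask"] = outdir / "nawm_mask.nii.gz"
    save_volume(files["nawm_mask"], ds.rois.nawm_mask.astype(np.uint8), vox)
    files["brain_mask"] = outdir / "brain_mask.nii.gz"
    save_volume(files["brain_mask"], ds.brain_mask.astype(np.uint8), vox)
    files["truth_b0"] = outdir / "truth_b0_ppm.nii.gz"
    save_volume(files["truth_b0"], ds.truth.b0_map_ppm, vox)
    files["truth_b1"] = outdir / "truth_b1_rel.nii.gz"
    save_volume(files["truth_b1"], ds.truth.b1_map_rel, vox)
    files["truth_labels"] = outdir / "truth_tissue_labels.nii.gz"
    save_volume(files["truth_labels"], ds.truth.tissue_labels.astype(np.int16), vox)
    for name, amp in ds.truth.pool_amplitude_maps.items():
        p = outdir / f"truth_amp_{name}.nii.gz"
        save_volume(p, amp, vox)
        files[f"truth_amp_{name}"] = p
    offsets_path = outdir / "offsets.json"
    write_offsets(offsets_path, config.offsets_ppm)
    files["offsets"] = offsets_path

    manifest = {
        "seed": config.seed,
        "grid_shape": list(config.grid_shape),
        "sat_powers_uT": list(config.sat_powers_uT),
        "files": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in sorted(files.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    _provenance(outdir, {"phantom": str(config)}, config.seed,
                {"simulate": time.perf_counter() - t0})
    return manifest


def run_process(config: RunConfig) -> dict[str, dict[float, ContrastMap]]:
    """Load inputs per the config, run the pipeline, write maps and QC."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if not config.series_paths:
        raise ValidationError("config lists no CEST series")
    if config.b1_map_path is None:
        raise ValidationError("B1 correction requested but no b1_map_path given")
    series_by_power = {}
    for power, path in config.series_paths.items():
        series_by_power[power] = load_cest_series(
            path, config.offsets_path, config.m0_path, power
        )
    ref = next(iter(series_by_power.values()))
    b1_rel = load_b1_map(config.b1_map_path, ref.grid_shape)
    mask = (load_mask(config.brain_mask_path, ref.grid_shape)
            if config.brain_mask_path else None)

    corrected = process_cest(series_by_power, b1_rel, mask, config.b1_correction)

    for name, by_power in corrected.items():
        for power, cmap in by_power.items():
            path = outdir / f"{name}_{power:.1f}uT.nii.gz"
            save_volume(path, cmap.values, ref.voxel_size_mm, ref.affine)
            save_volume(outdir / f"{name}_{power:.1f}uT_mask.nii.gz",
                        cmap.mask.astype(np.uint8), ref.voxel_size_mm, ref.affine)
            sidecar = {"contrast": name, "power_uT": power,
                       "n_valid_voxels": int(cmap.valid_mask.sum())}
            (outdir / f"{name}_{power:.1f}uT.json").write_text(
                json.dumps(sidecar, indent=2) + "\n")
    _provenance(outdir, {"run": config.__dict__}, config.seed,
                {"process": time.perf_counter() - t0})
    return corrected


def run_report(
    config: RunConfig,
    corrected: dict[str, dict[float, ContrastMap]] | None = None,
) -> dict:
    """Threshold-based heterogeneity report for one patient dataset."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if corrected is None:
        corrected = run_process(config)
    ref_map = next(iter(next(iter(corrected.values())).values()))
    shape = ref_map.values.shape
    tumour = load_mask(config.tumour_mask_path, shape)
    nawm = load_mask(config.nawm_mask_path, shape)
    rois = ROISet(tumour_mask=tumour, nawm_mask=nawm)

    reports = {}
    means_rows = []
    for name, by_power in corrected.items():
        for power, cmap in by_power.items():
            th = compute_threshold(cmap, nawm, config.threshold_multiplier)
            rep = hyperintense_map(cmap, tumour, th, patient_id=config.patient_id)
            key = f"{name}_{power:.1f}uT"
            reports[key] = rep
            rep.per_slice.to_csv(outdir / f"report_{key}_slices.csv", index=False)
            save_volume(outdir / f"hyper_{key}.nii.gz", rep.hyper_mask.astype(np.uint8))
            stats = roi_means(cmap, rois)
            for roi_name, row in stats.iterrows():
                means_rows.append({"contrast": name, "power_uT": power, "roi": roi_name,
                                   **row.to_dict()})
            summary = {
                "patient_id": rep.patient_id,
                "contrast": name,
                "power_uT": power,
                "threshold": th.threshold,
                "nawm_mean": th.nawm_mean,
                "nawm_sd": th.nawm_sd,
                "tumour_voxels": rep.tumour_voxels,
                "hyper_voxels": rep.hyper_voxels,
                "percent_whole": rep.percent_whole,
                "hyper_volume_ml": rep.hyper_volume_ml,
            }
            (outdir / f"report_{key}.json").write_text(json.dumps(summary, indent=2) + "\n")
    pd.DataFrame(means_rows).to_csv(outdir / "roi_means.csv", index=False)
    _provenance(outdir, {"run": config.__dict__}, config.seed,
                {"report": time.perf_counter() - t0})
    return reports


def summarise_cohort(percents, output_path=None) -> dict:
    """Group statistics of per-patient hyperintense percentages."""
    gs = group_summary(percents)
    out = {
        "n_patients": gs.n_patients,
        "mean_pct": gs.mean_pct,
        "sd_pct": gs.sd_pct,
        "min_pct": gs.min_pct,
        "max_pct": gs.max_pct,
    }
    if output_path is not None:
        Path(output_path).write_text(json.dumps(out, indent=2) + "\n")
    return out
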