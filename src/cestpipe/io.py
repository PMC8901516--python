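"""Readers/writers for the on-disk artefacts and their validated containers.

All volumes are NIfTI-1 (``.nii``/``.nii.gz``) via nibabel.  The offset
schedule lives in a sidecar file — JSON with an ``"offsets_ppm"`` key is the
canonical dialect, plain one-value-per-line text is accepted — because no
standard NIfTI header field carries CEST offsets.  The sidecar order is
authoritative and preserved end-to-end; all masks and maps must share the
exact grid of the series (registration is out of scope, so no implicit
resampling ever happens).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import acquisition


class ValidationError(ValueError):
    """Input files are inconsistent with each other or with the contract."""


@dataclass
class CESTSeries:
    """One 4D CEST acquisition at a single nominal saturation power.

    ``volumes[x, y, z, k]`` is the raw image at offset ``offsets_ppm[k]``;
    ``m0`` is the mean of the unsaturated reference acquisitions on the
    same grid.
    """

    volumes: np.ndarray
    offsets_ppm: np.ndarray
    m0: np.ndarray
    nominal_power_uT: float
    voxel_size_mm: tuple[float, float, float] = acquisition.VOXEL_SIZE_MM
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.offsets_ppm = acquisition.validate_offsets(self.offsets_ppm)
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.volumes.ndim != 4:
            raise ValidationError(
                f"CEST series must be 4D, got shape {self.volumes.shape}"
            )
        if self.volumes.shape[3] != self.offsets_ppm.size:
            raise ValidationError(
                f"offset count ({self.offsets_ppm.size}) does not match the "
                f"number of volumes ({self.volumes.shape[3]})"
            )
        if self.m0.shape != self.volumes.shape[:3]:
            raise ValidationError(
                f"M0 grid {self.m0.shape} does not match series grid "
                f"{self.volumes.shape[:3]}"
            )
        if self.nominal_power_uT <= 0:
            raise ValidationError("nominal_power_uT must be > 0")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[:3]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class ROISet:
    """Tumour and contralateral NAWM masks on the series grid."""

    tumour_mask: np.ndarray
    nawm_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = acquisition.VOXEL_SIZE_MM

    def __post_init__(self) -> None:
        self.tumour_mask = np.asarray(self.tumour_mask).astype(bool)
        self.nawm_mask = np.asarray(self.nawm_mask).astype(bool)
        if self.tumour_mask.shape != self.nawm_mask.shape:
            raise ValidationError("tumour and NAWM masks are on different grids")
        if np.any(self.tumour_mask & self.nawm_mask):
            raise ValidationError("tumour and NAWM masks overlap")


def read_offsets(path) -> np.ndarray:
    """Read an offset schedule sidecar (JSON or one-per-line text)."""
    path = Path(path)
    text = path.read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError:
        try:
            values = [float(line) for line in text.split() if line.strip()]
        except ValueError as exc:
            raise ValidationError(f"{path}: cannot parse offsets: {exc}") from None
    else:
        if isinstance(payload, dict):
            if "offsets_ppm" not in payload:
                raise ValidationError(f'{path}: JSON sidecar lacks an "offsets_ppm" key')
            values = payload["offsets_ppm"]
        else:
            values = payload
    try:
        return acquisition.validate_offsets(np.asarray(values, dtype=float))
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_offsets(path, offsets_ppm) -> None:
    path = Path(path)
    payload = {"offsets_ppm": [float(v) for v in np.asarray(offsets_ppm).ravel()]}
    path.write_text(json.dumps(payload, indent=2) + "\n")


def _load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine, img.header.get_zooms()


def save_volume(path, data, voxel_size_mm=acquisition.VOXEL_SIZE_MM, affine=None) -> None:
    """Write an array as NIfTI-1; NaNs are preserved as-is."""
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_cest_series(image_path, offsets_path, m0_path, nominal_power_uT) -> CESTSeries:
    """Assemble a validated :class:`CESTSeries` from its three files.

    The M0 file may hold a single 3D mean or a 4D stack of unsaturated
    acquisitions (then averaged along the 4th axis).  Non-positive M0
    voxels are permitted here; they are dropped from the processing mask at
    normalisation time with a logged count.
    """
    volumes, affine, zooms = _load_nifti(image_path)
    if volumes.ndim != 4:
        raise ValidationError(f"{image_path}: expected a 4D series, got shape {volumes.shape}")
    offsets = read_offsets(offsets_path)
    if offsets.size != volumes.shape[3]:
        raise ValidationError(
            f"{offsets_path}: {offsets.size} offsets but {image_path} holds "
            f"{volumes.shape[3]} volumes"
        )
    m0, _, _ = _load_nifti(m0_path)
    if m0.ndim == 4:
        m0 = m0.mean(axis=3)
    if m0.shape != volumes.shape[:3]:
        raise ValidationError(
            f"{m0_path}: M0 grid {m0.shape} does not match {image_path} grid "
            f"{volumes.shape[:3]} (axis mismatch)"
        )
    voxel = tuple(float(z) for z in zooms[:3])
    return CESTSeries(
        volumes=volumes,
        offsets_ppm=offsets,
        m0=m0,
        nominal_power_uT=float(nominal_power_uT),
        voxel_size_mm=voxel,
        affine=affine,
    )


def load_b1_map(path, reference_shape) -> np.ndarray:
    """Load a relative-B1 map (dimensionless, 1.0 = nominal power).

    Grid must match ``reference_shape`` exactly; non-positive values are
    not an error here — the B1-correction stage excludes them per voxel.
    """
    data, _, _ = _load_nifti(path)
    if data.shape != tuple(reference_shape):
        raise ValidationError(
            f"{path}: B1 map grid {data.shape} does not match series grid "
            f"{tuple(reference_shape)}"
        )
    return data


def load_mask(path, reference_shape) -> np.ndarray:
    """Load a 0/1 NIfTI mask as boolean; grid must match exactly."""
    data, _, _ = _load_nifti(path)
    if data.shape != tuple(reference_shape):
        raise ValidationError(
            f"{path}: mask grid {data.shape} does not match series grid "
            f"{tuple(reference_shape)}"
        )
    return data > 0.5
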