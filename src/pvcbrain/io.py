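"""NIfTI-1 input/output for volumes, atlases, and probability maps."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import LabelAtlas, ProbabilityMaps, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "read_probability_maps",
    "write_probability_maps",
]

logger = logging.getLogger(__name__)


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    ornt = nib.orientations.io_orientation(img.affine)
    if not np.allclose(ornt, nib.orientations.io_orientation(np.eye(4))):
        logger.info("reorienting %s to canonical (RAS) axes", path)
        img = nib.as_closest_canonical(img)
    return img


def _spacing_origin(img: nib.Nifti1Image):
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return tuple(float(z) for z in zooms), origin


def read_volume(path) -> VolumeImage:
    """Load a 3D NIfTI volume; spacing comes from the header zooms."""
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D data "
            f"(volumes must be 3D scalar grids)"
        )
    spacing, origin = _spacing_origin(img)
    return VolumeImage(data, spacing, origin)


def _affine(img: VolumeImage | LabelAtlas, spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(img: VolumeImage, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(img.values.astype(np.float32),
                          _affine(img, img.spacing, img.origin))
    nii.header.set_zooms(img.spacing)
    nib.save(nii, str(path))


def read_atlas(path, region_names: list[str] | None = None) -> LabelAtlas:
    """Load an integer label volume; names default to 'region_<j>'."""
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: atlas must be a 3D label volume")
    labels = np.rint(data).astype(np.int32)
    r = int(labels.max())
    if region_names is None:
        region_names = [f"region_{j:02d}" for j in range(1, r + 1)]
    return LabelAtlas(labels, tuple(region_names))


def write_atlas(atlas: LabelAtlas, path,
                spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(atlas.labels.astype(np.int16),
                          _affine(atlas, spacing, origin))
    nii.header.set_zooms(spacing)
    nib.save(nii, str(path))


def read_probability_maps(path, region_names: list[str] | None = None) -> ProbabilityMaps:
    """Load a 4D NIfTI with one 3D map per foreground region."""
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: probability maps must be 4D (x, y, z, region)")
    maps = np.moveaxis(data, -1, 0)
    if region_names is None:
        region_names = [f"region_{j:02d}" for j in range(1, maps.shape[0] + 1)]
    return ProbabilityMaps(np.clip(maps, 0.0, 1.0), tuple(region_names))


def write_probability_maps(probmaps: ProbabilityMaps, path,
                           spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.moveaxis(probmaps.maps, 0, -1).astype(np.float32)
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    nii = nib.Nifti1Image(data, aff)
    nii.header.set_zooms(tuple(spacing) + (1.0,))
    nib.save(nii, str(path))
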