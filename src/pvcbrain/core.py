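"""Core image containers and the Gaussian point-spread-function model.

A PET scanner's finite resolution is modelled as convolution with a 3D
Gaussian point spread function (PSF), conventionally parameterised by its
full width at half maximum (FWHM) in millimetres.  Everything downstream —
phantom simulation, Iterative Yang correction, evaluation — moves
:class:`VolumeImage` objects through that forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "LabelAtlas",
    "ProbabilityMaps",
    "PSFModel",
    "FWHM_TO_SIGMA",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "gaussian_blur",
]

#: FWHM = 2 sqrt(2 ln 2) * sigma for a Gaussian.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian FWHM (mm) to its standard deviation (mm).

    Raises
    ------
    ValueError
        If ``fwhm_mm`` is not strictly positive.
    """
    if not fwhm_mm > 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_mm!r}")
    return float(fwhm_mm) / FWHM_TO_SIGMA


def sigma_to_fwhm(sigma_mm: float) -> float:
    """Inverse of :func:`fwhm_to_sigma`."""
    if not sigma_mm > 0:
        raise ValueError(f"sigma must be positive, got {sigma_mm!r}")
    return float(sigma_mm) * FWHM_TO_SIGMA


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar field (SUV-scaled activity) on a regular grid.

    Parameters
    ----------
    values
        3D array of finite, typically non-negative intensities.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in millimetres.
    origin
        Physical position of voxel (0, 0, 0) in millimetres.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={arr.ndim}")
        if min(arr.shape) < 8:
            raise ValueError(f"grid dimensions must be >= 8 per axis, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("values must be finite")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing!r}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "VolumeImage":
        """Same grid, new intensities."""
        return VolumeImage(values, self.spacing, self.origin)


@dataclass(frozen=True)
class LabelAtlas:
    """Integer region parcellation on the same grid as a companion volume.

    Label 0 is background; foreground labels run 1..R and every foreground
    region must be non-empty.
    """

    labels: np.ndarray
    region_names: tuple[str, ...]

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        names = tuple(self.region_names)
        r = len(names)
        lmin, lmax = int(lab.min()), int(lab.max())
        if lmin < 0 or lmax > r:
            raise ValueError(f"labels must lie in [0, {r}], found range [{lmin}, {lmax}]")
        present = np.bincount(lab.ravel(), minlength=r + 1)
        empty = [names[j - 1] for j in range(1, r + 1) if present[j] == 0]
        if empty:
            raise ValueError(f"empty foreground region(s): {empty}")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "region_names", names)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class ProbabilityMaps:
    """Per-region membership weights P_j(x) in [0, 1].

    ``maps`` has shape (R, nx, ny, nz), one soft (or binary) map per
    foreground region.  At every voxel the foreground memberships sum to at
    most 1; the remainder is implicit background.
    """

    maps: np.ndarray
    region_names: tuple[str, ...]
    includes_background: bool = False

    _SUM_TOL = 1e-6

    def __post_init__(self):
        m = np.asarray(self.maps, dtype=np.float64)
        if m.ndim != 4:
            raise ValueError("maps must be a 4D (region, x, y, z) array")
        if m.shape[0] != len(self.region_names):
            raise ValueError(
                f"{m.shape[0]} maps but {len(self.region_names)} region names"
            )
        if m.min() < -self._SUM_TOL or m.max() > 1 + self._SUM_TOL:
            raise ValueError("map values must lie in [0, 1]")
        total = m.sum(axis=0)
        if total.max() > 1 + self._SUM_TOL:
            raise ValueError(
                f"per-voxel membership sums exceed 1 (max {total.max():.8f})"
            )
        object.__setattr__(self, "maps", np.clip(m, 0.0, 1.0))
        object.__setattr__(self, "region_names", tuple(self.region_names))

    @property
    def n_regions(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


@dataclass(frozen=True)
class PSFModel:
    """Per-axis Gaussian PSF, FWHM in millimetres.

    An axis FWHM of exactly 0 denotes a delta (identity) kernel along that
    axis; the all-zero PSF is the identity operator, used by tests and by
    configurations that disable blurring.
    """

    fwhm_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    truncation_radius: float = 4.0

    def __post_init__(self):
        f = tuple(float(v) for v in self.fwhm_mm)
        if len(f) != 3 or any(v < 0 for v in f):
            raise ValueError(f"FWHM values must be >= 0, got {self.fwhm_mm!r}")
        if self.truncation_radius < 3:
            raise ValueError("truncation_radius must be >= 3 sigmas")
        object.__setattr__(self, "fwhm_mm", f)

    @classmethod
    def isotropic(cls, fwhm_mm: float, truncation_radius: float = 4.0) -> "PSFModel":
        return cls((fwhm_mm, fwhm_mm, fwhm_mm), truncation_radius)

    @classmethod
    def delta(cls) -> "PSFModel":
        """The identity PSF (no blurring)."""
        return cls((0.0, 0.0, 0.0))

    @property
    def is_delta(self) -> bool:
        return all(v == 0 for v in self.fwhm_mm)

    def sigmas_vox(self, spacing: tuple[float, float, float]) -> tuple[float, float, float]:
        """Per-axis sigma in voxel units for a given grid spacing."""
        return tuple(
            (fwhm_to_sigma(f) / s) if f > 0 else 0.0
            for f, s in zip(self.fwhm_mm, spacing)
        )


def gaussian_blur(img: VolumeImage, psf: PSFModel) -> VolumeImage:
    """Convolve a volume with the Gaussian PSF (separable, per axis).

    Boundaries use edge replication so a constant image maps exactly to
    itself; the normalised kernel guarantees no intensity offset.  Axis
    FWHMs are interpreted in mm and divided by the voxel spacing, so
    anisotropic grids are handled per-axis.
    """
    if psf.is_delta:
        return img.with_values(img.values.copy())
    out = img.values
    for axis, sigma in enumerate(psf.sigmas_vox(img.spacing)):
        if sigma > 0:
            out = ndimage.gaussian_filter1d(
                out, sigma, axis=axis, mode="nearest", truncate=psf.truncation_radius
            )
    return img.with_values(out)
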