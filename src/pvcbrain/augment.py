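"""Laplacian-blending data augmentation.

New semi-realistic samples are composed from two existing phantoms by
multi-scale blending: both images are decomposed into Laplacian pyramids,
composited level-by-level under the Gaussian pyramid of a mask, and
reconstructed.  Blending the non-PVC and reference-PVC channels of a pair
with the *same* mask keeps the synthetic pair internally consistent, so it
can join the training set as if it were a new case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import PSFModel, VolumeImage, gaussian_blur
from .phantom import PairedSample

__all__ = [
    "BlendSpec",
    "build_laplacian_pyramid",
    "reconstruct_laplacian_pyramid",
    "blend",
    "hemisphere_mask",
    "axial_split_mask",
    "augment_pairs",
]

MASK_MODES = ("hemisphere", "axial", "supplied")

# 5-tap binomial smoothing kernel used for pyramid down/up sampling
_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class BlendSpec:
    """How synthetic pairs are composed: pyramid depth and mask family."""

    levels: int = 3
    mask_mode: str = "hemisphere"
    mask_smoothing_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.mask_mode not in MASK_MODES:
            raise ValueError(f"mask_mode must be one of {MASK_MODES}")


def _smooth(arr: np.ndarray) -> np.ndarray:
    for axis in range(arr.ndim):
        arr = ndimage.correlate1d(arr, _KERNEL, axis=axis, mode="nearest")
    return arr


def _downsample(arr: np.ndarray) -> np.ndarray:
    return _smooth(arr)[::2, ::2, ::2]


def _upsample(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    zoom = [t / s for t, s in zip(shape, arr.shape)]
    return ndimage.zoom(arr, zoom, order=1, mode="nearest", grid_mode=True)


def _check_levels(shape: tuple[int, ...], levels: int) -> None:
    max_levels = int(np.log2(min(shape)))
    if levels > max_levels:
        raise ValueError(
            f"{levels} pyramid levels too deep for grid {shape} "
            f"(max {max_levels})"
        )
    for dim in shape:
        if dim % (2 ** (levels - 1)) != 0:
            raise ValueError(
                f"grid dimension {dim} not divisible by 2^{levels - 1}"
            )


def build_laplacian_pyramid(img: VolumeImage, levels: int) -> list[np.ndarray]:
    """Band-pass decomposition: L_k = G_k - upsample(G_{k+1}).

    Returns ``levels`` arrays: ``levels - 1`` detail bands of decreasing
    size followed by the low-resolution residual.  Reconstruction by
    :func:`reconstruct_laplacian_pyramid` is exact by construction
    (telescoping sum), whatever the smoothing kernel.
    """
    _check_levels(img.shape, levels)
    gaussians = [img.values]
    for _ in range(levels - 1):
        gaussians.append(_downsample(gaussians[-1]))
    bands = [
        g - _upsample(g_next, g.shape)
        for g, g_next in zip(gaussians[:-1], gaussians[1:])
    ]
    bands.append(gaussians[-1])
    return bands


def reconstruct_laplacian_pyramid(bands: list[np.ndarray]) -> np.ndarray:
    out = bands[-1]
    for band in reversed(bands[:-1]):
        out = band + _upsample(out, band.shape)
    return out


def blend(img_a: VolumeImage, img_b: VolumeImage, mask: np.ndarray,
          levels: int = 3) -> VolumeImage:
    """Multi-scale composite: A where mask=1, B where mask=0, soft seam.

    Each Laplacian band of A and B is mixed under the matching Gaussian
    pyramid level of the mask, so the seam width adapts to the spatial
    scale of each band.
    """
    if img_a.shape != img_b.shape or mask.shape != img_a.shape:
        raise ValueError("images and mask must share one grid")
    mask = np.asarray(mask, dtype=np.float64)
    if mask.min() < 0 or mask.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    bands_a = build_laplacian_pyramid(img_a, levels)
    bands_b = build_laplacian_pyramid(img_b, levels)
    mask_pyr = [mask]
    for _ in range(levels - 1):
        mask_pyr.append(_downsample(mask_pyr[-1]))
    composite = [
        m * a + (1.0 - m) * b
        for m, a, b in zip(mask_pyr, bands_a, bands_b)
    ]
    return img_a.with_values(reconstruct_laplacian_pyramid(composite))


def hemisphere_mask(shape: tuple[int, int, int],
                    spacing: tuple[float, float, float],
                    smoothing_mm: float = 4.0) -> np.ndarray:
    """Left-right split along the first axis, smoothed to a soft seam."""
    mask = np.zeros(shape)
    mask[: shape[0] // 2] = 1.0
    if smoothing_mm > 0:
        mask = gaussian_blur(
            VolumeImage(mask, spacing), PSFModel.isotropic(smoothing_mm)
        ).values
    return np.clip(mask, 0.0, 1.0)


def axial_split_mask(shape: tuple[int, int, int],
                     spacing: tuple[float, float, float],
                     smoothing_mm: float = 4.0) -> np.ndarray:
    """Superior-inferior split along the last axis."""
    mask = np.zeros(shape)
    mask[..., : shape[2] // 2] = 1.0
    if smoothing_mm > 0:
        mask = gaussian_blur(
            VolumeImage(mask, spacing), PSFModel.isotropic(smoothing_mm)
        ).values
    return np.clip(mask, 0.0, 1.0)


def augment_pairs(samples: list[PairedSample], n_target: int,
                  spec: BlendSpec | None = None,
                  rng: np.random.Generator | None = None,
                  supplied_mask: np.ndarray | None = None) -> list[PairedSample]:
    """Grow a dataset to ``n_target`` samples by pairwise blending.

    Random ordered parent pairs are drawn; the non-PVC channels are blended
    with each other and the reference-PVC channels likewise, under the SAME
    mask, so pairs stay corresponding.  Synthetic samples carry no ground
    truth (``truth=None``) and are tagged in metadata.  If ``n_target`` is
    not above the current size the input list is returned unchanged.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to blend")
    if spec is None:
        spec = BlendSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if n_target <= len(samples):
        return list(samples)
    if spec.mask_mode == "supplied" and supplied_mask is None:
        raise ValueError("mask_mode='supplied' requires a mask")
    out = list(samples)
    shape = samples[0].nonpvc.shape
    spacing = samples[0].nonpvc.spacing
    while len(out) < n_target:
        ia, ib = rng.choice(len(samples), size=2, replace=False)
        a, b = samples[ia], samples[ib]
        if spec.mask_mode == "hemisphere":
            mask = hemisphere_mask(shape, spacing, spec.mask_smoothing_mm)
        elif spec.mask_mode == "axial":
            mask = axial_split_mask(shape, spacing, spec.mask_smoothing_mm)
        else:
            mask = np.asarray(supplied_mask, dtype=np.float64)
        mask_id = f"{spec.mask_mode}:{int(ia)}x{int(ib)}:{len(out)}"
        nonpvc = blend(a.nonpvc, b.nonpvc, mask, spec.levels)
        refpvc = blend(a.reference_pvc, b.reference_pvc, mask, spec.levels)
        nonpvc = nonpvc.with_values(np.maximum(nonpvc.values, 0.0))
        refpvc = refpvc.with_values(np.maximum(refpvc.values, 0.0))
        out.append(
            PairedSample(
                truth=None,
                nonpvc=nonpvc,
                reference_pvc=refpvc,
                atlas=a.atlas,
                probmaps=a.probmaps,
                metadata={
                    **a.metadata,
                    "augmented": True,
                    "parents": (int(ia), int(ib)),
                    "mask_id": mask_id,
                    "mask_id_nonpvc": mask_id,
                    "mask_id_pvc": mask_id,
                    "blend_levels": spec.levels,
                },
            )
        )
    return out
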