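"""Synthetic brain-like phantoms and the PET forward model.

Real paired PET/MRI data are not distributable, so training and evaluation
run on phantoms: nested-ellipsoid "brains" with a CSF shell, a cortical
grey-matter shell split into angular sectors, a white-matter core, and two
deep-grey nuclei.  Activities are piecewise-constant per region with four
named tracer profiles emulating the contrast patterns of common
neuroimaging radiotracers; the non-PVC observation is produced by Gaussian
PSF blurring plus variance-proportional (pseudo-Poisson) noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelAtlas, PSFModel, ProbabilityMaps, VolumeImage, gaussian_blur
from .iy import IYConfig, iy_correct

__all__ = [
    "PhantomSpec",
    "PairedSample",
    "TRACER_PROFILES",
    "make_atlas",
    "make_probability_maps",
    "assign_activities",
    "simulate_pet",
    "make_dataset",
]

# Per-profile activity ranges (SUV-like units) by region class.  Contrast
# patterns: fdg-like has a ~4:1 grey:white ratio; dopa-like concentrates in
# the deep (striatal) nuclei; amyloid-like has high white matter; tau-like
# has heterogeneous cortical uptake.
TRACER_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "fdg-like": {"csf": (0.1, 0.3), "cortex": (6.0, 8.0), "white": (1.5, 2.0), "deep": (6.0, 8.0)},
    "dopa-like": {"csf": (0.05, 0.2), "cortex": (1.5, 2.5), "white": (1.0, 1.5), "deep": (8.0, 12.0)},
    "amyloid-like": {"csf": (0.1, 0.3), "cortex": (2.0, 6.0), "white": (4.0, 6.0), "deep": (3.0, 5.0)},
    "tau-like": {"csf": (0.1, 0.3), "cortex": (2.0, 7.0), "white": (1.5, 2.5), "deep": (2.0, 4.0)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one family of phantoms.

    ``noise_level`` scales a zero-mean Gaussian term whose standard
    deviation follows sqrt(local mean), emulating Poisson-like count noise.
    A fixed ``seed`` makes every derived phantom bit-reproducible.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_sectors: int = 8
    tracer_profile: str = "fdg-like"
    noise_level: float = 0.02
    sim_psf_fwhm_mm: float = 6.0
    seed: int = 0
    # normalized radii of the nested shells (fractions of the brain radius)
    csf_inner: float = 0.88
    white_outer: float = 0.62

    def __post_init__(self):
        if min(self.shape) < 16:
            raise ValueError("phantom grid must be at least 16 voxels per axis")
        if self.n_sectors < 1:
            raise ValueError("need at least one cortical sector")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.tracer_profile not in TRACER_PROFILES:
            raise ValueError(
                f"unknown tracer profile {self.tracer_profile!r}; "
                f"valid profiles: {sorted(TRACER_PROFILES)}"
            )

    def region_names(self) -> tuple[str, ...]:
        sectors = tuple(f"cortex_sector_{i + 1:02d}" for i in range(self.n_sectors))
        return ("csf_shell",) + sectors + ("white_matter", "deep_grey_left", "deep_grey_right")


@dataclass
class PairedSample:
    """One training/evaluation unit: truth, observation, IY reference.

    ``truth`` is None for augmented (blended) samples, whose parents'
    ground truths do not blend consistently with the IY correction.
    """

    truth: VolumeImage | None
    nonpvc: VolumeImage
    reference_pvc: VolumeImage
    atlas: LabelAtlas
    probmaps: ProbabilityMaps
    metadata: dict = field(default_factory=dict)


def make_atlas(spec: PhantomSpec, angle_offset: float = 0.0) -> LabelAtlas:
    """Build the nested-ellipsoid parcellation for one phantom.

    Labels: 1 = CSF shell, 2..n+1 = cortical sectors (split by azimuthal
    angle, optionally rotated by ``angle_offset`` radians), n+2 = white
    matter, n+3/n+4 = deep-grey nuclei.  Raises if any requested sector
    would be empty at this resolution.
    """
    if min(spec.shape) < 32 and spec.n_sectors >= 8:
        raise ValueError("grids below 32^3 cannot resolve 8 or more sectors")
    names = spec.region_names()
    n = spec.n_sectors
    nx, ny, nz = spec.shape
    # normalized coordinates in [-1, 1] per axis over the brain ellipsoid
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    radii = (0.42 * nx, 0.45 * ny, 0.42 * nz)
    x, y, z = np.meshgrid(
        (np.arange(nx) - cx) / radii[0],
        (np.arange(ny) - cy) / radii[1],
        (np.arange(nz) - cz) / radii[2],
        indexing="ij",
    )
    rho = np.sqrt(x**2 + y**2 + z**2)
    labels = np.zeros(spec.shape, dtype=np.int32)

    brain = rho <= 1.0
    labels[brain & (rho > spec.csf_inner)] = 1  # CSF shell
    cortex = brain & (rho <= spec.csf_inner) & (rho > spec.white_outer)
    phi = np.mod(np.arctan2(y, x) - angle_offset, 2 * np.pi)
    sector = np.minimum((phi / (2 * np.pi) * n).astype(np.int32), n - 1)
    labels[cortex] = 2 + sector[cortex]
    labels[brain & (rho <= spec.white_outer)] = n + 2  # white matter core

    # two deep-grey nuclei inside the white matter, mirrored about x
    for k, sign in enumerate((-1.0, 1.0)):
        du = np.sqrt(((x - sign * 0.28) / 0.16) ** 2 + (y / 0.14) ** 2 + (z / 0.16) ** 2)
        labels[(du <= 1.0) & (labels == n + 2)] = n + 3 + k

    counts = np.bincount(labels.ravel(), minlength=len(names) + 1)
    for j, name in enumerate(names, start=1):
        if counts[j] == 0:
            raise ValueError(
                f"region {name!r} is empty at grid {spec.shape} with "
                f"{n} sectors; reduce the sector count or enlarge the grid"
            )
    return LabelAtlas(labels, names)


def make_probability_maps(atlas: LabelAtlas, smoothing_fwhm_mm: float = 0.0,
                          spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> ProbabilityMaps:
    """Binary indicator maps per region, optionally smoothed.

    With smoothing the indicators are blurred by a Gaussian and then
    renormalised voxel-wise wherever the voxel originally belonged to a
    foreground region, so the membership total stays exactly 1 inside the
    brain while boundaries become soft.
    """
    if smoothing_fwhm_mm < 0:
        raise ValueError("smoothing FWHM must be >= 0")
    r = atlas.n_regions
    maps = np.zeros((r,) + atlas.shape, dtype=np.float64)
    for j in range(1, r + 1):
        maps[j - 1] = atlas.labels == j
    if smoothing_fwhm_mm > 0:
        psf = PSFModel.isotropic(smoothing_fwhm_mm)
        for j in range(r):
            maps[j] = gaussian_blur(VolumeImage(maps[j], spacing), psf).values
        total = maps.sum(axis=0)
        inside = (atlas.labels > 0) & (total > 1e-12)
        scale = np.ones_like(total)
        scale[inside] = 1.0 / total[inside]
        maps *= scale
        np.clip(maps, 0.0, 1.0, out=maps)
    return ProbabilityMaps(maps, atlas.region_names)


def _region_class(name: str) -> str:
    if name.startswith("cortex"):
        return "cortex"
    if name.startswith("deep"):
        return "deep"
    if name.startswith("white"):
        return "white"
    return "csf"


def assign_activities(atlas: LabelAtlas, spec: PhantomSpec,
                      rng: np.random.Generator) -> VolumeImage:
    """Draw one activity per region from its tracer-profile class range.

    The result is piecewise-constant with background 0 — the noiseless
    ground truth the forward model degrades.
    """
    ranges = TRACER_PROFILES[spec.tracer_profile]
    lut = np.zeros(atlas.n_regions + 1)
    for j, name in enumerate(atlas.region_names, start=1):
        lo, hi = ranges[_region_class(name)]
        lut[j] = rng.uniform(lo, hi)
    return VolumeImage(lut[atlas.labels], spec.spacing)


def simulate_pet(truth: VolumeImage, psf: PSFModel, noise_level: float,
                 rng: np.random.Generator) -> VolumeImage:
    """Forward model: PSF blur, then pseudo-Poisson noise, clipped at 0.

    The noise term is zero-mean Gaussian with standard deviation
    ``noise_level * sqrt(blurred)`` — variance proportional to the local
    mean, the standard surrogate for count statistics in reconstructed PET.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if np.any(truth.values < 0):
        raise ValueError("truth activity must be non-negative")
    blurred = gaussian_blur(truth, psf).values
    if noise_level > 0:
        noise = rng.standard_normal(blurred.shape) * noise_level * np.sqrt(
            np.maximum(blurred, 0.0)
        )
        blurred = np.maximum(blurred + noise, 0.0)
    return truth.with_values(blurred)


def make_dataset(n: int, spec: PhantomSpec, iy_config: IYConfig | None = None,
                 seed: int | None = None) -> list[PairedSample]:
    """Generate ``n`` reproducible paired samples.

    Each sample gets its own atlas (sector boundaries randomly rotated),
    activity draw, and noise realisation; the IY reference is computed from
    binary probability maps with the recorded ``iy_config``.  Per-sample
    seeds are spawned deterministically from the master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if iy_config is None:
        iy_config = IYConfig()
    master = spec.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(n)
    samples: list[PairedSample] = []
    for i, child in enumerate(children):
        try:
            rng = np.random.default_rng(child)
            angle = rng.uniform(0, 2 * np.pi / max(spec.n_sectors, 1))
            atlas = make_atlas(spec, angle_offset=angle)
            probmaps = make_probability_maps(atlas, 0.0, spec.spacing)
            truth = assign_activities(atlas, spec, rng)
            sim_psf = (
                PSFModel.isotropic(spec.sim_psf_fwhm_mm)
                if spec.sim_psf_fwhm_mm > 0
                else PSFModel.delta()
            )
            nonpvc = simulate_pet(truth, sim_psf, spec.noise_level, rng)
            reference = iy_correct(nonpvc, probmaps, iy_config)
            samples.append(
                PairedSample(
                    truth=truth,
                    nonpvc=nonpvc,
                    reference_pvc=reference,
                    atlas=atlas,
                    probmaps=probmaps,
                    metadata={
                        "tracer_profile": spec.tracer_profile,
                        "master_seed": master,
                        "index": i,
                        "iy_iterations": iy_config.iterations,
                        "iy_fwhm_mm": iy_config.psf.fwhm_mm,
                        "augmented": False,
                    },
                )
            )
        except Exception as exc:  # annotate with the failing sample index
            raise RuntimeError(f"failed to construct sample {i}: {exc}") from exc
    return samples
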