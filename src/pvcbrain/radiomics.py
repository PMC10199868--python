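"""Region-wise radiomic features (20 features, 7 categories).

Conventional SUV indices, first-order histogram statistics, the area under
the cumulative SUV-volume histogram (AUC-CSH), and texture features from
four matrix families: grey-level co-occurrence (GLCM), run length (GLRLM),
neighbourhood grey-level difference (NGLDM, contrast), and zone length
(GLZLM).

Settings follow the common clinical-radiomics convention: fixed bin-number
discretisation (64 bins between region min and max), GLCM/GLRLM over the
13 unique 3D directions at distance 1 with symmetric accumulation and
per-direction features averaged, 26-connected zones, and the 26-neighbour
mean for the NGLDM neighbourhood.  Kurtosis is the Pearson moment ratio
mu4/sigma^4 (not excess) computed on the raw SUV values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelAtlas, VolumeImage

__all__ = [
    "RadiomicsSettings",
    "FEATURE_NAMES",
    "DIRECTIONS_3D",
    "discretize",
    "radiomics_features",
    "radiomics_table",
    "relative_error_heatmap",
]

FEATURE_NAMES: tuple[str, ...] = (
    "SUV_mean", "SUV_std", "SUV_max", "SUV_Q1", "SUV_Q2", "SUV_Q3", "TLG_mL",
    "HISTO_kurtosis", "HISTO_entropy_log10", "HISTO_entropy_log2", "HISTO_uniformity",
    "AUC_CSH",
    "GLCM_homogeneity", "GLCM_energy", "GLCM_dissimilarity",
    "GLRLM_run_percentage",
    "NGLDM_contrast",
    "GLZLM_SZE", "GLZLM_LGZE", "GLZLM_HGZE",
)

#: The 13 unique 3D offsets (up to sign) at Chebyshev distance 1.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass(frozen=True)
class RadiomicsSettings:
    n_bins: int = 64
    auc_csh_thresholds: int = 1000

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("need at least 2 grey-level bins")


def discretize(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, bool]:
    """Fixed-bin-number grey levels 1..n_bins between region min and max.

    The maximum value maps to level ``n_bins``.  A constant region maps
    entirely to level 1 and is flagged degenerate (second return value).
    """
    v = np.asarray(values, dtype=np.float64)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        return np.ones(v.shape, dtype=np.int64), True
    levels = np.floor(n_bins * (v - vmin) / (vmax - vmin)).astype(np.int64) + 1
    np.minimum(levels, n_bins, out=levels)
    return levels, False


def _shift_pairs(lv: np.ndarray, offset: tuple[int, int, int]):
    """Aligned (level_a, level_b) views of in-region voxel pairs at offset.

    ``lv`` is the whole-grid level array with 0 outside the region.
    """
    sl_a, sl_b = [], []
    for o, dim in zip(offset, lv.shape):
        if o >= 0:
            sl_a.append(slice(0, dim - o))
            sl_b.append(slice(o, dim))
        else:
            sl_a.append(slice(-o, dim))
            sl_b.append(slice(0, dim + o))
    a = lv[tuple(sl_a)]
    b = lv[tuple(sl_b)]
    both = (a > 0) & (b > 0)
    return a[both], b[both]


def _glcm_features(lv: np.ndarray, n_levels: int) -> dict[str, float]:
    """Homogeneity, energy, dissimilarity averaged over the 13 directions."""
    homog, energy, dissim = [], [], []
    for offset in DIRECTIONS_3D:
        a, b = _shift_pairs(lv, offset)
        if a.size == 0:
            continue
        # symmetric accumulation: count (i,j) and (j,i)
        mat = np.zeros((n_levels, n_levels))
        np.add.at(mat, (a - 1, b - 1), 1.0)
        np.add.at(mat, (b - 1, a - 1), 1.0)
        p = mat / mat.sum()
        i, j = np.indices(p.shape)
        absdiff = np.abs(i - j)
        homog.append(float((p / (1.0 + absdiff)).sum()))
        energy.append(float((p**2).sum()))
        dissim.append(float((p * absdiff).sum()))
    if not homog:
        return {"GLCM_homogeneity": np.nan, "GLCM_energy": np.nan,
                "GLCM_dissimilarity": np.nan}
    return {
        "GLCM_homogeneity": float(np.mean(homog)),
        "GLCM_energy": float(np.mean(energy)),
        "GLCM_dissimilarity": float(np.mean(dissim)),
    }


def _glrlm_run_percentage(lv: np.ndarray, n_voxels: int) -> float:
    """Run percentage = (number of runs) / (number of region voxels),
    averaged over the 13 directions.

    A run starts wherever the predecessor along the direction is outside
    the region or holds a different grey level, so counting run starts
    counts runs without materialising the full run-length matrix.
    """
    rps = []
    for offset in DIRECTIONS_3D:
        pred = np.zeros_like(lv)
        sl_dst, sl_src = [], []
        for o, dim in zip(offset, lv.shape):
            if o >= 0:
                sl_dst.append(slice(o, dim))
                sl_src.append(slice(0, dim - o))
            else:
                sl_dst.append(slice(0, dim + o))
                sl_src.append(slice(-o, dim))
        pred[tuple(sl_dst)] = lv[tuple(sl_src)]
        starts = (lv > 0) & (pred != lv)
        rps.append(float(starts.sum()) / n_voxels)
    return float(np.mean(rps))


def _ngldm_contrast(lv: np.ndarray, mask: np.ndarray, n_levels: int) -> float:
    """NGLDM/NGTDM-style contrast with the 26-neighbour mean level.

    For each grey level i, s_i accumulates |i - mean neighbour level| over
    region voxels of level i that have at least one in-region neighbour;
    contrast couples the level-probability spread with the mean absolute
    neighbourhood difference.  Single-level regions give 0.
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(lv.astype(np.float64), kernel, mode="constant")
    nb_cnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant")
    valid = mask & (nb_cnt > 0)
    if not np.any(valid):
        return float("nan")
    levels = lv[valid]
    diffs = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
    n_i = np.bincount(levels, minlength=n_levels + 1)[1:].astype(np.float64)
    s_i = np.bincount(levels, weights=diffs, minlength=n_levels + 1)[1:]
    n_vc = float(n_i.sum())
    p_i = n_i / n_vc
    occupied = np.nonzero(n_i)[0]
    n_gp = occupied.size
    if n_gp <= 1:
        return 0.0
    grid = (occupied[:, None] + 1 - (occupied[None, :] + 1)) ** 2
    spread = float((p_i[occupied][:, None] * p_i[occupied][None, :] * grid).sum())
    return spread / (n_gp * (n_gp - 1)) * float(s_i.sum()) / n_vc


def _glzlm_features(lv: np.ndarray, n_levels: int) -> dict[str, float]:
    """Zone features with 26-connected zones of equal grey level."""
    structure = np.ones((3, 3, 3), dtype=int)
    zone_levels, zone_sizes = [], []
    for level in range(1, n_levels + 1):
        binary = lv == level
        if not binary.any():
            continue
        labelled, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labelled.ravel())[1:]
        zone_levels.extend([level] * n_zones)
        zone_sizes.extend(sizes.tolist())
    levels = np.asarray(zone_levels, dtype=np.float64)
    sizes = np.asarray(zone_sizes, dtype=np.float64)
    nz = levels.size
    return {
        "GLZLM_SZE": float(np.mean(1.0 / sizes**2)) if nz else np.nan,
        "GLZLM_LGZE": float(np.mean(1.0 / levels**2)) if nz else np.nan,
        "GLZLM_HGZE": float(np.mean(levels**2)) if nz else np.nan,
    }


def _auc_csh(values: np.ndarray, n_thresholds: int) -> float:
    """Area under the cumulative SUV-volume histogram.

    x-axis: threshold as a fraction of the intensity range; y-axis:
    fraction of the region volume at or above the threshold.  Both axes
    normalised to [0, 1]; trapezoidal integration.  A constant region has
    the whole volume above every threshold: AUC = 1.
    """
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        return 1.0
    fracs = np.linspace(0.0, 1.0, n_thresholds)
    thresholds = vmin + fracs * (vmax - vmin)
    sorted_vals = np.sort(values)
    above = values.size - np.searchsorted(sorted_vals, thresholds, side="left")
    return float(np.trapezoid(above / values.size, fracs))


def radiomics_features(img: VolumeImage, region_mask: np.ndarray,
                       settings: RadiomicsSettings | None = None) -> dict[str, float]:
    """All 20 features for one region.

    Returns a dict keyed by :data:`FEATURE_NAMES` plus a ``degenerate``
    flag (True when the region holds a single intensity, in which case the
    texture features take their closed-form degenerate values).
    """
    if settings is None:
        settings = RadiomicsSettings()
    mask = np.asarray(region_mask, dtype=bool)
    if mask.sum() < 8:
        raise ValueError(f"region too small for radiomics ({int(mask.sum())} voxels, need >= 8)")
    vals = img.values[mask]
    n = vals.size
    voxel_ml = img.voxel_volume_mm3 / 1000.0

    feats: dict[str, float] = {
        "SUV_mean": float(vals.mean()),
        "SUV_std": float(vals.std(ddof=0)),
        "SUV_max": float(vals.max()),
        "SUV_Q1": float(np.percentile(vals, 25)),
        "SUV_Q2": float(np.percentile(vals, 50)),
        "SUV_Q3": float(np.percentile(vals, 75)),
        "TLG_mL": float(vals.mean() * n * voxel_ml),
    }

    # Pearson kurtosis on the raw values; undefined for zero variance
    sd = vals.std(ddof=0)
    feats["HISTO_kurtosis"] = (
        float(np.mean((vals - vals.mean()) ** 4) / sd**4) if sd > 0 else float("nan")
    )

    levels_region, degenerate = discretize(vals, settings.n_bins)
    counts = np.bincount(levels_region, minlength=settings.n_bins + 1)[1:]
    p = counts[counts > 0] / n
    feats["HISTO_entropy_log2"] = float(-(p * np.log2(p)).sum())
    feats["HISTO_entropy_log10"] = float(-(p * np.log10(p)).sum())
    feats["HISTO_uniformity"] = float((p**2).sum())
    feats["AUC_CSH"] = _auc_csh(vals, settings.auc_csh_thresholds)

    lv = np.zeros(img.shape, dtype=np.int64)
    lv[mask] = levels_region
    feats.update(_glcm_features(lv, settings.n_bins))
    feats["GLRLM_run_percentage"] = _glrlm_run_percentage(lv, n)
    feats["NGLDM_contrast"] = _ngldm_contrast(lv, mask, settings.n_bins)
    feats.update(_glzlm_features(lv, settings.n_bins))
    feats["degenerate"] = degenerate
    return feats


def radiomics_table(img: VolumeImage, atlas: LabelAtlas,
                    settings: RadiomicsSettings | None = None,
                    min_voxels: int = 8) -> pd.DataFrame:
    """Region x feature table over all foreground atlas regions.

    Regions below ``min_voxels`` are skipped with a NaN row.
    """
    rows = []
    for j, name in enumerate(atlas.region_names, start=1):
        mask = atlas.labels == j
        row: dict = {"region_id": j, "region": name, "n_voxels": int(mask.sum())}
        if mask.sum() >= min_voxels:
            row.update(radiomics_features(img, mask, settings))
        else:
            row.update({f: np.nan for f in FEATURE_NAMES})
            row["degenerate"] = True
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def relative_error_heatmap(ref_table: pd.DataFrame, pred_table: pd.DataFrame,
                           lr_average: bool = False) -> pd.DataFrame:
    """Percent error 100*(pred - ref)/ref per region and feature.

    Cells where the reference value is 0 become NaN (flagged, never
    infinite).  With ``lr_average`` homologous regions whose names differ
    only by a ``_left``/``_right`` suffix are averaged into one row.
    """
    if not ref_table.index.equals(pred_table.index):
        raise ValueError("region sets of the two tables differ")
    cols = [c for c in FEATURE_NAMES if c in ref_table.columns]
    if [c for c in FEATURE_NAMES if c not in ref_table.columns]:
        raise ValueError("tables are missing expected feature columns")
    ref = ref_table[cols].astype(float)
    pred = pred_table[cols].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = 100.0 * (pred - ref) / ref
    err = err.mask(ref == 0)
    if lr_average:
        base = err.index.str.replace(r"_(left|right)$", "", regex=True)
        err = err.groupby(base).mean()
        err.index.name = "region"
    return err
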