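"""Image-similarity metrics and region-wise agreement analysis.

Covers the whole-image battery (RMSE, PSNR, SSIM, joint histograms) and
the region-wise SUV agreement tools (Bland-Altman limits of agreement,
region-mean scatter with OLS fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import LabelAtlas, VolumeImage

__all__ = [
    "MetricReport",
    "BlandAltmanResult",
    "rmse",
    "psnr",
    "ssim",
    "ssim2d",
    "joint_histogram",
    "bland_altman",
    "region_suv_table",
    "metric_report",
]


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, VolumeImage) else np.asarray(img, dtype=np.float64)


def rmse(a, b, mask: np.ndarray | None = None) -> float:
    """Root-mean-square error over the mask (default: whole grid)."""
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError("images must share one grid")
    diff = av - bv
    if mask is not None:
        if not np.any(mask):
            raise ValueError("empty mask")
        diff = diff[mask]
    return float(np.sqrt(np.mean(diff**2)))


def psnr(a, b, data_range: float | None = None,
         mask: np.ndarray | None = None) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf.

    ``data_range`` defaults to the maximum of the reference image ``a``.
    """
    av, bv = _values(a), _values(b)
    if data_range is None:
        data_range = float(av.max())
    if not data_range > 0:
        raise ValueError("data_range must be > 0")
    diff = av - bv
    if mask is not None:
        diff = diff[mask]
    mse = float(np.mean(diff**2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def _ssim_map(a: np.ndarray, b: np.ndarray, data_range: float,
              sigma: float, k1: float, k2: float, truncate: float):
    """Local SSIM map plus the border pad that must be cropped."""
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    win_size = 2 * int(truncate * sigma + 0.5) + 1
    if min(a.shape) < win_size:
        raise ValueError(f"window ({win_size}) larger than grid {a.shape}")

    def filt(x):
        return ndimage.gaussian_filter(x, sigma, truncate=truncate, mode="reflect")

    ns = win_size ** a.ndim
    cov_norm = ns / (ns - 1)  # sample covariance
    ux, uy = filt(a), filt(b)
    uxx, uyy, uxy = filt(a * a), filt(b * b), filt(a * b)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    return s, (win_size - 1) // 2


def ssim(a, b, data_range: float | None = None, mask: np.ndarray | None = None,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03,
         truncate: float = 3.5) -> float:
    """Structural similarity with a Gaussian local window (sigma = 1.5).

    The local SSIM map is averaged over the (border-cropped) grid, or over
    the supplied brain mask intersected with the valid interior.
    """
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError("images must share one grid")
    if data_range is None:
        data_range = float(max(av.max(), bv.max()) - min(av.min(), bv.min()))
        if data_range == 0:
            return 1.0
    s, pad = _ssim_map(av, bv, data_range, sigma, k1, k2, truncate)
    interior = tuple(slice(pad, dim - pad) for dim in s.shape)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)[interior]
        if not np.any(m):
            raise ValueError("mask has no voxels in the window-valid interior")
        return float(s[interior][m].mean())
    return float(s[interior].mean())


def ssim2d(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """SSIM for a single 2D slice (same window settings)."""
    return ssim(a, b, data_range=data_range)


def joint_histogram(a, b, bins: int = 64,
                    value_range: tuple[float, float] | None = None,
                    mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """2D histogram of paired voxel intensities over the brain mask.

    Returns ``(counts, bin_edges)``; total counts equal the mask size.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    av, bv = _values(a), _values(b)
    if mask is not None:
        av, bv = av[mask], bv[mask]
    else:
        av, bv = av.ravel(), bv.ravel()
    if value_range is None:
        lo = min(av.min(), bv.min())
        hi = max(av.max(), bv.max())
        value_range = (lo, hi if hi > lo else lo + 1.0)
    counts, edges, _ = np.histogram2d(av, bv, bins=bins,
                                      range=[value_range, value_range])
    return counts, edges


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement summary: bias and 95% limits of agreement."""

    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(ref_vals, pred_vals) -> BlandAltmanResult:
    """Bland-Altman analysis of paired values (differences = pred - ref).

    Limits of agreement are mean +- 1.96 x sample SD (n-1 denominator).
    """
    ref = np.asarray(ref_vals, dtype=np.float64)
    pred = np.asarray(pred_vals, dtype=np.float64)
    if ref.shape != pred.shape:
        raise ValueError("ref and pred must have equal length")
    n = ref.size
    if n < 2:
        raise ValueError("need at least 2 paired values")
    diffs = pred - ref
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, n)


def region_suv_table(ref: VolumeImage, pred: VolumeImage,
                     atlas: LabelAtlas) -> tuple[pd.DataFrame, dict]:
    """Per-region SUV_mean for both volumes plus scatter statistics.

    Returns a table (one row per foreground region; empty regions are
    flagged) and OLS statistics of pred-on-ref region means: slope,
    intercept, R^2, and the RMSE of the region means.
    """
    if ref.shape != pred.shape or atlas.shape != ref.shape:
        raise ValueError("volumes and atlas must share one grid")
    rows = []
    for j, name in enumerate(atlas.region_names, start=1):
        m = atlas.labels == j
        if not np.any(m):
            rows.append({"region_id": j, "region": name, "suv_mean_ref": np.nan,
                         "suv_mean_pred": np.nan, "n_voxels": 0, "empty": True})
            continue
        rows.append({
            "region_id": j,
            "region": name,
            "suv_mean_ref": float(ref.values[m].mean()),
            "suv_mean_pred": float(pred.values[m].mean()),
            "n_voxels": int(m.sum()),
            "empty": False,
        })
    table = pd.DataFrame(rows)
    valid = table[~table["empty"]]
    x = valid["suv_mean_ref"].to_numpy()
    y = valid["suv_mean_pred"].to_numpy()
    if x.size >= 2 and np.ptp(x) > 0:
        fit = stats.linregress(x, y)
        fit_stats = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2),
            "rmse_region_means": float(np.sqrt(np.mean((y - x) ** 2))),
        }
    else:
        fit_stats = {
            "slope": float("nan"), "intercept": float("nan"),
            "r_squared": 1.0 if np.allclose(x, y) else float("nan"),
            "rmse_region_means": float(np.sqrt(np.mean((y - x) ** 2))) if x.size else float("nan"),
        }
    return table, fit_stats


@dataclass(frozen=True)
class MetricReport:
    """SSIM/PSNR/RMSE for a set of volume pairs, with mean +- SD."""

    ssim_values: tuple[float, ...]
    psnr_values: tuple[float, ...]
    rmse_values: tuple[float, ...]

    def summary(self) -> dict[str, float]:
        out = {}
        for name, vals in (("ssim", self.ssim_values), ("psnr", self.psnr_values),
                           ("rmse", self.rmse_values)):
            arr = np.asarray(vals, dtype=np.float64)
            finite = arr[np.isfinite(arr)]
            out[f"{name}_mean"] = float(finite.mean()) if finite.size else float("nan")
            out[f"{name}_sd"] = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
        return out


def metric_report(pairs, mask_fn=None) -> MetricReport:
    """Evaluate SSIM/PSNR/RMSE over (reference, predicted) volume pairs."""
    s_vals, p_vals, r_vals = [], [], []
    for ref, pred in pairs:
        mask = mask_fn(ref) if mask_fn is not None else None
        dr = float(ref.values.max())
        s_vals.append(ssim(ref, pred, data_range=dr, mask=mask))
        p_vals.append(psnr(ref, pred, data_range=dr, mask=mask))
        r_vals.append(rmse(ref, pred, mask=mask))
    return MetricReport(tuple(s_vals), tuple(p_vals), tuple(r_vals))
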