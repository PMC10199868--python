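"""Voxel-wise group statistics with family-wise error control.

A mass-univariate two-sample t-test compares two groups of co-registered
volumes voxel by voxel; multiple testing over the brain mask is controlled
with a Bonferroni family-wise error (FWE) correction.  Bonferroni is a
conservative, dependency-free stand-in for random-field-theory FWE; a
paired-test option is provided for designs where the same subjects appear
in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import VolumeImage

__all__ = ["TTestResult", "voxelwise_ttest"]


@dataclass(frozen=True)
class TTestResult:
    """Voxel-wise t map plus the FWE-thresholded summary.

    ``over_mask`` marks voxels where group A is significantly *higher*
    than group B (positive t), ``under_mask`` significantly lower; the two
    are disjoint subsets of the analysis mask.  Counts, percentages, and
    the mean +- SD of significant |t| summarise the result the way a
    voxel-based analysis table reports it.
    """

    t_map: np.ndarray
    analysis_mask: np.ndarray
    sig_mask: np.ndarray
    over_mask: np.ndarray
    under_mask: np.ndarray
    alpha: float
    correction: str
    df: int
    n_mask_voxels: int
    n_sig: int
    n_over: int
    n_under: int
    pct_over: float
    pct_under: float
    mean_abs_t_sig: float
    sd_abs_t_sig: float


def voxelwise_ttest(group_a: list[VolumeImage], group_b: list[VolumeImage],
                    alpha: float = 0.05, correction: str = "bonferroni",
                    mask: np.ndarray | None = None,
                    paired: bool = False) -> TTestResult:
    """Per-voxel two-sample (pooled-variance) t-test between two groups.

    Voxels where both groups have zero variance get t = 0.  With
    ``correction='bonferroni'`` the voxel-wise threshold is
    ``alpha / n_mask_voxels``; with ``'none'`` it is ``alpha``.  The
    default is the unpaired pooled test even for paired acquisitions;
    ``paired=True`` switches to a paired (one-sample-on-differences) test.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 volumes")
    shape = group_a[0].shape
    for img in group_a + group_b:
        if img.shape != shape:
            raise ValueError("all volumes must share one grid")
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")

    a = np.stack([img.values for img in group_a])
    b = np.stack([img.values for img in group_b])
    na, nb = a.shape[0], b.shape[0]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty analysis mask")

    if paired:
        if na != nb:
            raise ValueError("paired test requires equal group sizes")
        d = a - b
        df = na - 1
        sd = d.std(axis=0, ddof=1)
        denom = sd / np.sqrt(na)
        num = d.mean(axis=0)
    else:
        df = na + nb - 2
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        num = a.mean(axis=0) - b.mean(axis=0)

    t_map = np.zeros(shape)
    nonzero = denom > 0
    t_map[nonzero] = num[nonzero] / denom[nonzero]

    threshold = alpha / n_vox if correction == "bonferroni" else alpha
    # two-sided critical value at the corrected level
    t_crit = stats.t.isf(threshold / 2.0, df)
    sig = mask & (np.abs(t_map) > t_crit)
    over = sig & (t_map > 0)
    under = sig & (t_map < 0)
    abs_sig = np.abs(t_map[sig])
    return TTestResult(
        t_map=t_map,
        analysis_mask=mask,
        sig_mask=sig,
        over_mask=over,
        under_mask=under,
        alpha=alpha,
        correction=correction,
        df=df,
        n_mask_voxels=n_vox,
        n_sig=int(sig.sum()),
        n_over=int(over.sum()),
        n_under=int(under.sum()),
        pct_over=100.0 * over.sum() / n_vox,
        pct_under=100.0 * under.sum() / n_vox,
        mean_abs_t_sig=float(abs_sig.mean()) if abs_sig.size else float("nan"),
        sd_abs_t_sig=float(abs_sig.std(ddof=1)) if abs_sig.size > 1 else 0.0,
    )
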