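"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by direct enumeration (python
loops over voxels, pairs, runs, and zones) so the vectorised package
implementations can be checked against a genuinely separate code path.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def dense_gaussian_blur(img: np.ndarray, sigmas_vox, truncate: float = 4.0) -> np.ndarray:
    """Direct dense-kernel 3D convolution with edge-replication padding."""
    kernels = []
    for sigma in sigmas_vox:
        if sigma <= 0:
            kernels.append(np.array([1.0]))
            continue
        radius = int(truncate * sigma + 0.5)
        x = np.arange(-radius, radius + 1, dtype=float)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        kernels.append(k / k.sum())
    kernel3 = (
        kernels[0][:, None, None] * kernels[1][None, :, None] * kernels[2][None, None, :]
    )
    rx, ry, rz = (len(k) // 2 for k in kernels)
    padded = np.pad(img, ((rx, rx), (ry, ry), (rz, rz)), mode="edge")
    out = np.zeros_like(img, dtype=float)
    nx, ny, nz = img.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                block = padded[i : i + 2 * rx + 1, j : j + 2 * ry + 1, k : k + 2 * rz + 1]
                out[i, j, k] = float((block * kernel3).sum())
    return out


def in_region(mask: np.ndarray, p) -> bool:
    i, j, k = p
    if i < 0 or j < 0 or k < 0:
        return False
    if i >= mask.shape[0] or j >= mask.shape[1] or k >= mask.shape[2]:
        return False
    return bool(mask[i, j, k])


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    """Per-direction symmetric co-occurrence matrices, features averaged."""
    homog, energy, dissim = [], [], []
    coords = list(zip(*np.nonzero(mask)))
    for d in DIRECTIONS:
        mat = np.zeros((n_levels, n_levels))
        for (i, j, k) in coords:
            q = (i + d[0], j + d[1], k + d[2])
            if in_region(mask, q):
                a = levels[i, j, k] - 1
                b = levels[q] - 1
                mat[a, b] += 1
                mat[b, a] += 1
        if mat.sum() == 0:
            continue
        p = mat / mat.sum()
        h = e = ds = 0.0
        for a in range(n_levels):
            for b in range(n_levels):
                h += p[a, b] / (1 + abs(a - b))
                e += p[a, b] ** 2
                ds += p[a, b] * abs(a - b)
        homog.append(h)
        energy.append(e)
        dissim.append(ds)
    return {
        "GLCM_homogeneity": float(np.mean(homog)),
        "GLCM_energy": float(np.mean(energy)),
        "GLCM_dissimilarity": float(np.mean(dissim)),
    }


def glrlm_run_percentage(levels: np.ndarray, mask: np.ndarray) -> float:
    """Count maximal runs per direction by explicit line walking."""
    n_voxels = int(mask.sum())
    coords = list(zip(*np.nonzero(mask)))
    rps = []
    for d in DIRECTIONS:
        n_runs = 0
        for (i, j, k) in coords:
            prev = (i - d[0], j - d[1], k - d[2])
            if in_region(mask, prev) and levels[prev] == levels[i, j, k]:
                continue  # not a run start
            n_runs += 1
        rps.append(n_runs / n_voxels)
    return float(np.mean(rps))


def ngldm_contrast(levels: np.ndarray, mask: np.ndarray) -> float:
    """NGTDM-style contrast with the 26-neighbour mean, explicit loops."""
    s: dict[int, float] = {}
    n: dict[int, int] = {}
    for (i, j, k) in zip(*np.nonzero(mask)):
        nb = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    q = (i + di, j + dj, k + dk)
                    if in_region(mask, q):
                        nb.append(levels[q])
        if not nb:
            continue
        lev = int(levels[i, j, k])
        s[lev] = s.get(lev, 0.0) + abs(lev - sum(nb) / len(nb))
        n[lev] = n.get(lev, 0) + 1
    n_vc = sum(n.values())
    occupied = sorted(n)
    n_gp = len(occupied)
    if n_gp <= 1:
        return 0.0
    spread = 0.0
    for a in occupied:
        for b in occupied:
            spread += (n[a] / n_vc) * (n[b] / n_vc) * (a - b) ** 2
    return spread / (n_gp * (n_gp - 1)) * sum(s.values()) / n_vc


def glzlm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    """Zones by explicit 26-connected flood fill."""
    visited = np.zeros(mask.shape, dtype=bool)
    zones = []  # (level, size)
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        lev = levels[start]
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            i, j, k = p
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        q = (i + di, j + dj, k + dk)
                        if (
                            in_region(mask, q)
                            and not visited[q]
                            and levels[q] == lev
                        ):
                            visited[q] = True
                            stack.append(q)
        zones.append((int(lev), size))
    nz = len(zones)
    return {
        "GLZLM_SZE": sum(1.0 / sz**2 for _, sz in zones) / nz,
        "GLZLM_LGZE": sum(1.0 / lv**2 for lv, _ in zones) / nz,
        "GLZLM_HGZE": sum(float(lv**2) for lv, _ in zones) / nz,
    }


def histogram_features(values: np.ndarray, levels_region: np.ndarray) -> dict:
    """First-order statistics by direct summation."""
    n = values.size
    counts: dict[int, int] = {}
    for lev in levels_region:
        counts[int(lev)] = counts.get(int(lev), 0) + 1
    probs = [c / n for c in counts.values()]
    ent2 = -sum(p * math.log2(p) for p in probs)
    ent10 = -sum(p * math.log10(p) for p in probs)
    unif = sum(p * p for p in probs)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    kurt = (
        (sum((v - mean) ** 4 for v in values) / n) / var**2 if var > 0 else float("nan")
    )
    return {
        "HISTO_entropy_log2": ent2,
        "HISTO_entropy_log10": ent10,
        "HISTO_uniformity": unif,
        "HISTO_kurtosis": kurt,
    }


def per_voxel_ttest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t at every voxel via scipy, one by one."""
    from scipy import stats

    shape = a.shape[1:]
    t = np.zeros(shape)
    for idx in np.ndindex(shape):
        xa = a[(slice(None),) + idx]
        xb = b[(slice(None),) + idx]
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            t[idx] = 0.0
        else:
            t[idx] = stats.ttest_ind(xa, xb, equal_var=True).statistic
    return t
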