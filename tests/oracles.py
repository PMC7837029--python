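"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double/triple loops straight from the
defining formulas, deliberately sharing no code with the package, so each
test is a genuine two-route check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def haralick_oracle(p: np.ndarray) -> dict[str, float]:
    """Double-loop evaluation of the Haralick sums on a normalized matrix."""
    n = p.shape[0]
    contrast = dissim = homog = energy = entropy = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = 0.0
    for i in range(n):
        for j in range(n):
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
    corr_num = 0.0
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            contrast += (i - j) ** 2 * v
            dissim += abs(i - j) * v
            homog += v / (1 + (i - j) ** 2)
            energy += v * v
            if v > 0:
                entropy -= v * math.log2(v)
            corr_num += (i - mu_i) * (j - mu_j) * v
    sigma = math.sqrt(var_i) * math.sqrt(var_j)
    return {
        "contrast": contrast,
        "homogeneity": homog,
        "dissimilarity": dissim,
        "entropy": entropy,
        "energy": energy,
        "correlation": corr_num / sigma if sigma > 0 else float("nan"),
    }


def glcm_feature_oracle(p: np.ndarray) -> dict[str, float]:
    """Double-loop evaluation of the PET GLCM features."""
    n = p.shape[0]
    mu = 0.0
    for i in range(n):
        for j in range(n):
            mu += i * p[i, j]
    invdiff = var = 0.0
    for i in range(n):
        for j in range(n):
            invdiff += p[i, j] / (1 + abs(i - j))
            var += (i - mu) ** 2 * p[i, j]
    h = haralick_oracle(p)
    return {
        "inverse_difference": invdiff,
        "angular_second_moment": h["energy"],
        "variance": var,
        "correlation": h["correlation"],
        "entropy": h["entropy"],
        "dissimilarity": h["dissimilarity"],
    }


def rank_cooccurrence_oracle(
    rank_map: np.ndarray, adjacency: str = "8", levels: int = 10
) -> np.ndarray:
    """Enumerate every ordered adjacent ranked-tile pair, then normalize."""
    offs = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    if adjacency == "8":
        offs += [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    counts = np.zeros((levels, levels))
    rows, cols = rank_map.shape
    for r in range(rows):
        for c in range(cols):
            if np.isnan(rank_map[r, c]):
                continue
            for dr, dc in offs:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and not np.isnan(rank_map[r2, c2]):
                    counts[int(rank_map[r, c]), int(rank_map[r2, c2])] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm3d_oracle(
    bins: np.ndarray, voi: np.ndarray, direction: tuple[int, int, int], levels: int
) -> np.ndarray | None:
    """Voxel-by-voxel pair enumeration for one direction, symmetrized."""
    counts = np.zeros((levels, levels))
    nx, ny, nz = bins.shape
    found = False
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not voi[x, y, z]:
                    continue
                x2, y2, z2 = x + direction[0], y + direction[1], z + direction[2]
                if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz and voi[x2, y2, z2]:
                    a, b = bins[x, y, z], bins[x2, y2, z2]
                    counts[a, b] += 1
                    counts[b, a] += 1
                    found = True
    if not found:
        return None
    return counts / counts.sum()


def ngldm_oracle(bins: np.ndarray, voi: np.ndarray) -> dict[str, float]:
    """Literal transcription of the coarseness/contrast/busyness formulas."""
    nx, ny, nz = bins.shape
    n_v = int(voi.sum())
    levels = sorted({int(bins[i]) for i in zip(*np.where(voi))})
    p = {lev: float((bins[voi] == lev).sum()) / n_v for lev in levels}
    s = {lev: 0.0 for lev in levels}
    any_nb = False
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not voi[x, y, z]:
                    continue
                nb = []
                for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    x2, y2, z2 = x + dx, y + dy, z + dz
                    if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz and voi[x2, y2, z2]:
                        nb.append(int(bins[x2, y2, z2]))
                if nb:
                    any_nb = True
                    s[int(bins[x, y, z])] += abs(
                        int(bins[x, y, z]) - sum(nb) / len(nb)
                    )
    if not any_nb:
        raise ValueError("no voxel with an in-VOI neighbor")
    ps = sum(p[i] * s[i] for i in levels)
    coarseness = min(1e6, 1.0 / ps) if ps > 0 else 1e6
    n_g = len(levels)
    if n_g < 2:
        return {"coarseness": coarseness, "contrast": float("nan"),
                "busyness": float("nan")}
    contrast = (
        sum(p[i] * p[j] * (i - j) ** 2 for i in levels for j in levels)
        / (n_g * (n_g - 1))
    ) * (sum(s.values()) / n_v)
    denom = sum(
        abs(i * p[i] - j * p[j]) for i in levels for j in levels if i != j
    )
    busyness = ps / denom if denom > 0 else float("nan")
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness}


def histogram_oracle(bin_indices: np.ndarray) -> dict[str, float]:
    """Histogram entropy/uniformity plus moment shape stats by loops."""
    n = len(bin_indices)
    counts: dict[int, int] = {}
    for b in bin_indices:
        counts[int(b)] = counts.get(int(b), 0) + 1
    entropy = uniformity = 0.0
    for c in counts.values():
        f = c / n
        uniformity += f * f
        entropy -= f * math.log2(f)
    mean = sum(bin_indices) / n
    m2 = sum((b - mean) ** 2 for b in bin_indices) / n
    if m2 <= 0:
        skew = kurt = float("nan")
    else:
        m3 = sum((b - mean) ** 3 for b in bin_indices) / n
        m4 = sum((b - mean) ** 4 for b in bin_indices) / n
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3
    return {"skewness": skew, "kurtosis": kurt, "entropy": entropy,
            "uniformity": uniformity}


def cox_loglik_oracle(
    beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Written-out Cox partial log-likelihood (distinct times, 1 covariate)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def logrank_oracle(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> float:
    """Two-group log-rank chi-square via the O-E / V closed form."""
    o_minus_e = 0.0
    v = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v


def mann_whitney_u_oracle(g0: np.ndarray, g1: np.ndarray) -> float:
    """U for group 0 counted pair by pair with half credit for ties."""
    u = 0.0
    for a in g0:
        for b in g1:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def mann_whitney_p_oracle(g0: np.ndarray, g1: np.ndarray) -> float:
    """Exhaustive two-sided permutation p for |U - mean(U)|."""
    pooled = np.concatenate([g0, g1])
    n0 = len(g0)
    mean_u = n0 * len(g1) / 2.0
    obs = abs(mann_whitney_u_oracle(g0, g1) - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n0):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        total += 1
        if abs(mann_whitney_u_oracle(a, b) - mean_u) >= obs - 1e-12:
            count += 1
    return count / total


def auc_threshold_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC from the empirical ROC built threshold by threshold."""
    cuts = np.r_[np.inf, np.sort(np.unique(scores))[::-1], -np.inf]
    pts = []
    for c in cuts:
        pred = scores >= c
        tpr = pred[labels == 1].mean() if (labels == 1).any() else 0.0
        fpr = pred[labels == 0].mean() if (labels == 0).any() else 0.0
        pts.append((fpr, tpr))
    pts = sorted(set(pts))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return auc
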