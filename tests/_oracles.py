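"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy.ndimage and the package's own code paths:
labeling is an explicit flood fill, the perimeter is a per-pixel count of
exposed unit edges, and the unsharp oracle is a directly summed dense
convolution on an edge-padded array.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label components by explicit stack-based flood fill, raster order."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    labels = np.zeros((h, w), dtype=np.int32)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels


def crack_perimeter(labels: np.ndarray, label: int) -> int:
    """Count exposed unit edges of one component, pixel by pixel."""
    member = labels == label
    h, w = member.shape
    edges = 0
    for r in range(h):
        for c in range(w):
            if member[r, c]:
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not member[rr, cc]:
                        edges += 1
    return edges


def brute_particle_stats(mask: np.ndarray, connectivity: int = 8):
    """(area, perimeter, circularity) per component via the flood-fill oracle."""
    labels = flood_fill_label(mask, connectivity)
    out = []
    for lab in range(1, labels.max() + 1):
        area = int((labels == lab).sum())
        perim = crack_perimeter(labels, lab)
        circ = min(1.0, 4.0 * math.pi * area / perim**2)
        out.append((area, perim, circ))
    return out


def brute_filtered_area(mask, size_min, size_max, circ_min, circ_max, connectivity=8):
    """Total retained particle area by direct predicate evaluation."""
    return sum(
        a
        for a, _, c in brute_particle_stats(mask, connectivity)
        if size_min <= a <= size_max and circ_min <= c <= circ_max
    )


def gaussian_kernel_1d(sigma: float, half_width: int) -> np.ndarray:
    x = np.arange(-half_width, half_width + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def dense_unsharp(img: np.ndarray, sigma: float, weight: float, half_width: int) -> np.ndarray:
    """Unsharp mask via an explicitly summed dense 2-D convolution.

    Edge-replicate padding; returns the clipped, half-up-rounded uint8
    result so it can be compared with the pipeline's output.
    """
    f = np.asarray(img, dtype=np.float64)
    k1 = gaussian_kernel_1d(sigma, half_width)
    kernel = np.outer(k1, k1)
    padded = np.pad(f, half_width, mode="edge")
    h, w = f.shape
    blurred = np.zeros_like(f)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(2 * half_width + 1):
                for j in range(2 * half_width + 1):
                    acc += kernel[i, j] * padded[r + i, c + j]
            blurred[r, c] = acc
    sharp = (f - weight * blurred) / (1.0 - weight)
    return np.floor(np.clip(sharp, 0, 255) + 0.5).astype(np.uint8)


def ols_interaction_pvalue(ages_a, scores_a, ages_b, scores_b):
    """Slope-difference p-value by explicit normal-equations least squares."""
    from scipy import stats

    x = np.concatenate([np.asarray(ages_a, float), np.asarray(ages_b, float)])
    y = np.concatenate([np.asarray(scores_a, float), np.asarray(scores_b, float)])
    g = np.concatenate([np.zeros(len(ages_a)), np.ones(len(ages_b))])
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = math.sqrt(sigma2 * xtx_inv[3, 3])
    t = beta[3] / se
    return float(beta[3]), float(2 * stats.t.sf(abs(t), df))
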