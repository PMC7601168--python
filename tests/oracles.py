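"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: plain
Python loops and literal summations, so they can serve as references.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_pairs(window: np.ndarray, offset=(0, 1), symmetric=True) -> np.ndarray:
    """Count co-occurring gray-level pairs by explicit enumeration."""
    window = np.asarray(window)
    dr, dc = offset
    h, w = window.shape
    counts = np.zeros((256, 256), dtype=np.float64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[window[r, c], window[r2, c2]] += 1
                if symmetric:
                    counts[window[r2, c2], window[r, c]] += 1
    return counts / counts.sum()


def haralick_features(p: np.ndarray) -> dict[str, float]:
    """Literal summation of the ten texture features from a normalized p."""
    nz = list(zip(*np.nonzero(p)))
    px = [sum(p[i, j] for j in range(256)) for i in range(256)]
    py = [sum(p[i, j] for i in range(256)) for j in range(256)]
    p_sum = [0.0] * 511
    p_diff = [0.0] * 256
    for i, j in nz:
        p_sum[i + j] += p[i, j]
        p_diff[abs(i - j)] += p[i, j]
    mu_x = sum(i * px[i] for i in range(256))
    mu_y = sum(j * py[j] for j in range(256))
    sigma_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(256)))
    sigma_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(256)))

    f1 = sum(p[i, j] ** 2 for i, j in nz)
    f2 = sum(n * n * p_diff[n] for n in range(256))
    if sigma_x * sigma_y > 0:
        f3 = (sum(i * j * p[i, j] for i, j in nz) - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        f3 = 0.0
    f4 = sum((i - mu_x) ** 2 * p[i, j] for i, j in nz)
    f5 = sum(p[i, j] / (1.0 + (i - j) ** 2) for i, j in nz)
    f6 = sum(k * p_sum[k] for k in range(511))
    f8 = -sum(v * math.log(v) for v in p_sum if v > 0)
    f7 = sum((k - f8) ** 2 * p_sum[k] for k in range(511))
    f9 = -sum(p[i, j] * math.log(p[i, j]) for i, j in nz)
    mean_diff = sum(k * p_diff[k] for k in range(256))
    f10 = sum((k - mean_diff) ** 2 * p_diff[k] for k in range(256))
    return {
        "asm": f1,
        "contrast": f2,
        "correlation": f3,
        "variance": f4,
        "idm": f5,
        "sum_average": f6,
        "sum_variance": f7,
        "sum_entropy": f8,
        "entropy": f9,
        "difference_variance": f10,
    }


def hough_accumulator(edges: np.ndarray, radii) -> dict[tuple[int, int, int], float]:
    """Brute-force circle scores over every (row, col, radius) triple.

    score = (edge pixels within half a pixel of the circle) / (2 pi r).
    Only intended for tiny instances.
    """
    ys, xs = np.nonzero(edges)
    h, w = edges.shape
    scores = {}
    for r in radii:
        for cr in range(h):
            for cc in range(w):
                d = np.sqrt((ys - cr) ** 2 + (xs - cc) ** 2)
                votes = int((np.abs(d - r) <= 0.5).sum())
                scores[(cr, cc, r)] = votes / (2 * math.pi * r)
    return scores
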