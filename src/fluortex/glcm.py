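"""Gray-level co-occurrence matrices and Haralick texture features.

Each super-pixel is summarized by the joint distribution ``p(i, j)`` of
gray-level pairs at a fixed pixel displacement.  All 256 gray levels
are kept (no requantization), so the matrix is 256x256 and fine
intensity texture is preserved.  The default displacement is (0, 1):
horizontal neighbors at distance 1 (the 0-degree direction);
accumulation is symmetric (each pair is counted in both orders), which
makes the marginals equal and the matrix symmetric.

Ten scalar features are computed from ``p``:

======  ==========================  =============================================
f1      angular second moment       sum p^2 (uniformity / energy)
f2      contrast                    sum_n n^2 * P(|i-j| = n)
f3      correlation                 (sum ij p - mu_x mu_y) / (sigma_x sigma_y)
f4      variance (sum of squares)   sum (i - mu_x)^2 p
f5      inverse difference moment   sum p / (1 + (i-j)^2)
f6      sum average                 sum k p_{x+y}(k)
f7      sum variance                sum (k - f8)^2 p_{x+y}(k)
f8      sum entropy                 -sum p_{x+y} log p_{x+y}
f9      entropy                     -sum p log p
f10     difference variance         variance of p_{x-y}
======  ==========================  =============================================

Conventions: natural logarithm, 0*log(0) := 0, gray levels indexed
0..255, so ``k`` runs over [0, 510] for ``p_{x+y}`` and [0, 255] for
``p_{x-y}``.  Two further features used by some texture rankings,
difference entropy and the first information measure of correlation,
are available behind the ``extra`` flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import GrayImage
from .quadtree import LABEL_UNLABELED, SuperPixelGrid

__all__ = [
    "CooccMatrix",
    "HaralickFeatures",
    "cooccurrence",
    "haralick",
    "extract_features",
    "FEATURE_COLUMNS",
    "EXTRA_FEATURE_COLUMNS",
]

NG = 256  # gray levels

FEATURE_COLUMNS = [
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
]

EXTRA_FEATURE_COLUMNS = ["difference_entropy", "info_correlation"]


@dataclass
class CooccMatrix:
    """Normalized 256x256 co-occurrence distribution with its marginals.

    Derived quantities (computed once at construction): marginals
    ``px``/``py``, diagonal sums ``p_sum[k] = P(i+j = k)`` for k in
    [0, 510], cross sums ``p_diff[k] = P(|i-j| = k)`` for k in [0, 255],
    and the marginal moments ``mu_x, mu_y, sigma_x, sigma_y``.
    """

    p: np.ndarray
    offset: tuple[int, int] = (0, 1)
    symmetric: bool = True
    px: np.ndarray = field(init=False, repr=False)
    py: np.ndarray = field(init=False, repr=False)
    p_sum: np.ndarray = field(init=False, repr=False)
    p_diff: np.ndarray = field(init=False, repr=False)
    mu_x: float = field(init=False)
    mu_y: float = field(init=False)
    sigma_x: float = field(init=False)
    sigma_y: float = field(init=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (NG, NG):
            raise ValueError(f"co-occurrence matrix must be {NG}x{NG}")
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"co-occurrence matrix must be normalized, sums to {total}")
        levels = np.arange(NG, dtype=np.float64)
        self.px = self.p.sum(axis=1)
        self.py = self.p.sum(axis=0)
        # P(i+j=k): accumulate anti-diagonals; P(|i-j|=k): accumulate offsets
        self.p_sum = np.zeros(2 * NG - 1)
        self.p_diff = np.zeros(NG)
        for d in range(-(NG - 1), NG):
            diag = np.diagonal(self.p, offset=d)  # entries with j - i = d
            self.p_diff[abs(d)] += diag.sum()
            i0 = max(0, -d)
            k = 2 * np.arange(i0, i0 + diag.size) + d  # i + j along this diagonal
            np.add.at(self.p_sum, k, diag)
        self.mu_x = float(levels @ self.px)
        self.mu_y = float(levels @ self.py)
        self.sigma_x = float(np.sqrt(((levels - self.mu_x) ** 2) @ self.px))
        self.sigma_y = float(np.sqrt(((levels - self.mu_y) ** 2) @ self.py))


@dataclass
class HaralickFeatures:
    """The ten co-occurrence texture statistics of one super-pixel."""

    asm: float
    contrast: float
    correlation: float
    variance: float
    idm: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    entropy: float
    difference_variance: float
    difference_entropy: float = float("nan")
    info_correlation: float = float("nan")
    degenerate: bool = False  # constant window: correlation undefined, reported 0

    def as_array(self, extra: bool = False) -> np.ndarray:
        vals = [getattr(self, name) for name in FEATURE_COLUMNS]
        if extra:
            vals += [self.difference_entropy, self.info_correlation]
        return np.asarray(vals)


def cooccurrence(
    window: GrayImage | np.ndarray,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
) -> CooccMatrix:
    """Count gray-level pairs at *offset* over all in-bounds positions.

    With ``symmetric=True`` each pair also votes in reversed order,
    which is the convention assumed by the feature formulas (it makes
    ``mu_x = mu_y`` and ``sigma_x = sigma_y``).
    """
    arr = window.pixels if isinstance(window, GrayImage) else np.asarray(window)
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("window intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    dr, dc = offset
    h, w = arr.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError(f"window {arr.shape} too small for offset {offset}")
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = arr[r0:r1, c0:c1].astype(np.int64)
    b = arr[r0 + dr : r1 + dr, c0 + dc : c1 + dc].astype(np.int64)
    counts = np.bincount((a * NG + b).ravel(), minlength=NG * NG).astype(np.float64)
    counts = counts.reshape(NG, NG)
    if symmetric:
        counts = counts + counts.T
    return CooccMatrix(counts / counts.sum(), offset=offset, symmetric=symmetric)


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln(p) with the 0*log(0) := 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def haralick(m: CooccMatrix, extra: bool = False) -> HaralickFeatures:
    """Evaluate the ten texture features of a co-occurrence matrix.

    A constant window yields a single-entry matrix with zero marginal
    spread; its correlation is undefined and is reported as 0 with the
    ``degenerate`` flag set.
    """
    p = m.p
    levels = np.arange(NG, dtype=np.float64)
    k_sum = np.arange(2 * NG - 1, dtype=np.float64)
    k_diff = np.arange(NG, dtype=np.float64)

    f1 = float((p**2).sum())
    f2 = float((k_diff**2) @ m.p_diff)
    ij = np.outer(levels, levels)
    degenerate = m.sigma_x * m.sigma_y == 0.0
    if degenerate:
        f3 = 0.0
    else:
        f3 = float(((ij * p).sum() - m.mu_x * m.mu_y) / (m.sigma_x * m.sigma_y))
    f4 = float((((levels - m.mu_x)[:, None] ** 2) * p).sum())
    diff2 = (levels[:, None] - levels[None, :]) ** 2
    f5 = float((p / (1.0 + diff2)).sum())
    f6 = float(k_sum @ m.p_sum)
    f8 = float(-_xlogx(m.p_sum).sum())
    f7 = float(((k_sum - f8) ** 2) @ m.p_sum)
    f9 = float(-_xlogx(p).sum())
    mean_diff = float(k_diff @ m.p_diff)
    f10 = float(((k_diff - mean_diff) ** 2) @ m.p_diff)

    feats = HaralickFeatures(
        f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, degenerate=degenerate
    )
    if extra:
        feats.difference_entropy = float(-_xlogx(m.p_diff).sum())
        hx = float(-_xlogx(m.px).sum())
        hy = float(-_xlogx(m.py).sum())
        # HXY1 = -sum p(i,j) log(px(i) py(j))
        outer = np.outer(m.px, m.py)
        nz = (p > 0) & (outer > 0)
        hxy1 = float(-(p[nz] * np.log(outer[nz])).sum())
        denom = max(hx, hy)
        feats.info_correlation = (f9 - hxy1) / denom if denom > 0 else 0.0
    return feats


def extract_features(
    image: GrayImage,
    grid: SuperPixelGrid,
    image_id: str = "image",
    group_id: int | str = 0,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
    extra: bool = False,
) -> pd.DataFrame:
    """Per-super-pixel feature table for one labeled grid.

    Returns one row per valid, labeled window with identifier columns
    (``image_id, group_id, window_row, window_col, label``) followed by
    the feature columns.  Emits a warning and an empty table when the
    grid has no valid labeled windows.
    """
    cols = FEATURE_COLUMNS + (EXTRA_FEATURE_COLUMNS if extra else [])
    rows = []
    for i, (r0, c0, hs, ws) in enumerate(grid.windows):
        if not grid.valid[i] or grid.labels[i] == LABEL_UNLABELED:
            continue
        window = image.pixels[r0 : r0 + hs, c0 : c0 + ws]
        feats = haralick(cooccurrence(window, offset, symmetric), extra=extra)
        rows.append(
            {
                "image_id": image_id,
                "group_id": group_id,
                "window_row": int(r0 // grid.leaf_size),
                "window_col": int(c0 // grid.leaf_size),
                "label": int(grid.labels[i]),
                **dict(zip(cols, feats.as_array(extra=extra))),
            }
        )
    if not rows:
        warnings.warn(f"no valid labeled windows in {image_id}", stacklevel=2)
        return pd.DataFrame(
            columns=["image_id", "group_id", "window_row", "window_col", "label"] + cols
        )
    return pd.DataFrame(rows)
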