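"""Fixed-depth quadtree division into equal-size super-pixels.

A quadtree split halves both sides at each level, so subdividing to a
fixed leaf side ``s`` on an image whose sides are multiples of ``s`` is
exactly the uniform ``s x s`` tiling; the implementation tiles directly
and the recursive subdivision is kept as a cross-check (see
:func:`quadtree_divide_recursive`).  Images whose sides are not
multiples of the leaf size are zero-padded on the bottom/right, and any
window that overlaps padding — or the blanked exterior left by device
removal — is flagged invalid and excluded from feature extraction.

Class labels follow a biopsy-oriented rule: a super-pixel is anomalous
only when every one of its pixels lies inside the ground-truth
anomalous region; a single standard pixel makes the window standard, so
flagged windows are entirely lesion tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imaging import GrayImage, LabelMask

__all__ = [
    "SuperPixelGrid",
    "quadtree_divide",
    "quadtree_divide_recursive",
    "label_superpixels",
    "LABEL_STANDARD",
    "LABEL_ANOMALOUS",
    "LABEL_UNLABELED",
]

LABEL_STANDARD = 0
LABEL_ANOMALOUS = 1
LABEL_UNLABELED = -1


@dataclass
class SuperPixelGrid:
    """Row-major grid of square leaf windows tiling a (padded) image.

    ``windows[i] = (row0, col0, size, size)`` is a half-open pixel
    window; ``valid[i]`` is False for windows touching padding or
    unusable pixels; ``labels[i]`` is -1 (unlabeled), 0 (standard) or
    1 (anomalous).
    """

    leaf_size: int
    grid_rows: int
    grid_cols: int
    windows: np.ndarray  # (n, 4) int
    valid: np.ndarray  # (n,) bool
    labels: np.ndarray  # (n,) int8

    def __post_init__(self) -> None:
        n = self.grid_rows * self.grid_cols
        if len(self.windows) != n or len(self.valid) != n or len(self.labels) != n:
            raise ValueError("grid arrays must have grid_rows*grid_cols entries")

    @property
    def n_windows(self) -> int:
        return self.grid_rows * self.grid_cols

    def window_index(self, gr: int, gc: int) -> int:
        return gr * self.grid_cols + gc

    def to_frame(self):
        """Grid as a DataFrame (window index, row0, col0, valid, label)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "window": np.arange(self.n_windows),
                "row0": self.windows[:, 0],
                "col0": self.windows[:, 1],
                "valid": self.valid,
                "label": self.labels,
            }
        )


def _check_leaf_size(leaf_size: int) -> None:
    if leaf_size < 2 or (leaf_size & (leaf_size - 1)) != 0:
        raise ValueError(f"leaf_size must be a power of 2 >= 2, got {leaf_size}")


def quadtree_divide(image: GrayImage, leaf_size: int = 64) -> SuperPixelGrid:
    """Divide an image into ``leaf_size``-square super-pixel windows.

    The image is conceptually zero-padded up to the next multiple of
    ``leaf_size`` per side; windows are enumerated row-major over the
    padded extent.  Windows extending past the original image, or
    overlapping pixels flagged unusable by device removal, get
    ``valid=False``.
    """
    _check_leaf_size(leaf_size)
    h, w = image.shape
    grid_rows = -(-h // leaf_size)
    grid_cols = -(-w // leaf_size)
    if grid_rows == 0 or grid_cols == 0:
        raise ValueError("leaf_size larger than padded image")
    windows = np.empty((grid_rows * grid_cols, 4), dtype=np.int64)
    valid = np.ones(grid_rows * grid_cols, dtype=bool)
    i = 0
    for gr in range(grid_rows):
        for gc in range(grid_cols):
            r0, c0 = gr * leaf_size, gc * leaf_size
            windows[i] = (r0, c0, leaf_size, leaf_size)
            if r0 + leaf_size > h or c0 + leaf_size > w:
                valid[i] = False
            elif image.usable is not None and not image.usable[
                r0 : r0 + leaf_size, c0 : c0 + leaf_size
            ].all():
                valid[i] = False
            i += 1
    labels = np.full(grid_rows * grid_cols, LABEL_UNLABELED, dtype=np.int8)
    return SuperPixelGrid(leaf_size, grid_rows, grid_cols, windows, valid, labels)


def quadtree_divide_recursive(side: int, leaf_size: int) -> list[tuple[int, int]]:
    """Window origins from literal recursive 4-way subdivision.

    Only defined for square power-of-two extents (each split needs even
    sides).  Used to check the tiling equivalence of
    :func:`quadtree_divide`; returns origins in row-major sorted order.
    """
    _check_leaf_size(leaf_size)
    if side < leaf_size or (side & (side - 1)) != 0:
        raise ValueError("side must be a power of 2 >= leaf_size")

    out: list[tuple[int, int]] = []

    def split(r0: int, c0: int, size: int) -> None:
        if size == leaf_size:
            out.append((r0, c0))
            return
        half = size // 2
        for dr in (0, half):
            for dc in (0, half):
                split(r0 + dr, c0 + dc, half)

    split(0, 0, side)
    return sorted(out)


def label_superpixels(grid: SuperPixelGrid, mask: LabelMask) -> SuperPixelGrid:
    """Attach class labels to the grid's valid windows from ground truth.

    A valid window is labeled anomalous iff *all* of its pixels carry
    mask label 1; any standard pixel makes the window standard.  Invalid
    windows stay unlabeled.
    """
    labels = np.full(grid.n_windows, LABEL_UNLABELED, dtype=np.int8)
    mh, mw = mask.shape
    for i, (r0, c0, hs, ws) in enumerate(grid.windows):
        if not grid.valid[i]:
            continue
        if r0 + hs > mh or c0 + ws > mw:
            raise ValueError(
                f"mask shape {mask.shape} does not cover valid window {i}"
            )
        block = mask.labels[r0 : r0 + hs, c0 : c0 + ws]
        labels[i] = LABEL_ANOMALOUS if bool((block == 1).all()) else LABEL_STANDARD
    return replace(grid, labels=labels)
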