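"""Detection and removal of the circular imaging-device aperture.

Handheld fluorescence visualization devices leave a bright circular
aperture rim in many captured frames, surrounded by a near-black border
that carries no tissue information.  A circular Hough transform over the
edge map locates the aperture; when a sufficiently complete circle is
found the frame is cropped to its bounding square and the exterior is
blanked.  Frames without a device circle pass through unchanged — the
absence of a circle is a valid outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import hough_circle, hough_circle_peaks

from .edges import EdgeMap
from .imaging import GrayImage

__all__ = ["CircleHit", "hough_circles", "remove_device", "circle_crop"]

#: Fraction of the circumference that must vote for a circle to count
#: as a detected aperture.
DEFAULT_SCORE_FLOOR = 0.35

#: Default radius search range as a fraction of min(height, width).
DEFAULT_R_MIN_FRAC = 0.30
DEFAULT_R_MAX_FRAC = 0.48


@dataclass
class CircleHit:
    """One candidate aperture circle.

    ``score`` is the accumulator vote count normalized by the number of
    discrete circumference points, so a geometrically complete circle
    scores near 1 and fragmentary arcs score proportionally less.
    """

    center_row: int
    center_col: int
    radius: int
    score: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


def hough_circles(
    edges: EdgeMap | np.ndarray,
    r_min: int,
    r_max: int,
    r_step: int = 1,
    min_score: float = 0.10,
    max_hits: int = 5,
) -> list[CircleHit]:
    """Rank candidate circles in an edge map, best score first.

    Each edge pixel votes, for each candidate radius, into a 2-D center
    accumulator; accumulator peaks normalized by circumference length
    become :class:`CircleHit` entries.  Returns an empty list when no
    peak reaches ``min_score``.
    """
    edge_arr = edges.edges if isinstance(edges, EdgeMap) else np.asarray(edges, bool)
    h, w = edge_arr.shape
    limit = min(h, w) // 2 + max(r_step, 2)
    if not (0 < r_min <= r_max) or r_max > limit or r_step < 1:
        raise ValueError(
            f"invalid radius range [{r_min}, {r_max}] step {r_step} "
            f"for a {h}x{w} map (max allowed {limit})"
        )
    if not edge_arr.any():
        return []
    radii = np.arange(r_min, r_max + 1, r_step)
    accum = hough_circle(edge_arr, radii)  # normalized by circumference
    _, cxs, cys, rads = hough_circle_peaks(
        accum, radii, total_num_peaks=max_hits, normalize=False
    )
    hits = []
    for col, row, rad in zip(cxs, cys, rads):
        score = float(accum[np.searchsorted(radii, rad), row, col])
        if score >= min_score and 0 <= row < h and 0 <= col < w:
            hits.append(CircleHit(int(row), int(col), int(rad), min(score, 1.0)))
    hits.sort(key=lambda hit: hit.score, reverse=True)
    return hits


def circle_crop(
    arr: np.ndarray, hit: CircleHit, fill: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Crop *arr* to the circle's bounding square, blanking the exterior.

    Returns ``(cropped, inside)`` where ``inside`` flags pixels within
    the circle.  The bounding square is clipped at the array bounds, so
    the crop may be smaller than ``(2r+1)**2`` for circles near a border.
    """
    r0 = max(hit.center_row - hit.radius, 0)
    r1 = min(hit.center_row + hit.radius + 1, arr.shape[0])
    c0 = max(hit.center_col - hit.radius, 0)
    c1 = min(hit.center_col + hit.radius + 1, arr.shape[1])
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    inside = (rows - hit.center_row) ** 2 + (cols - hit.center_col) ** 2 <= hit.radius**2
    out = np.where(inside, arr[r0:r1, c0:c1], fill)
    return out.astype(arr.dtype), inside


def remove_device(
    image: GrayImage,
    hits: list[CircleHit],
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> GrayImage:
    """Extract the oral-cavity region inside the best aperture circle.

    When the best hit's score reaches ``score_floor``, pixels outside
    the circle are set to 0 and the image is cropped to the circle's
    bounding square; the returned image carries a ``usable`` mask of the
    circle interior so later windowing can skip the blank exterior.
    Otherwise the input passes through unchanged (device-absent case).
    """
    if not hits or hits[0].score < score_floor:
        return image
    hit = hits[0]
    cropped, inside = circle_crop(image.pixels, hit, fill=0)
    if image.usable is not None:
        prev, _ = circle_crop(image.usable.astype(np.uint8), hit, fill=0)
        inside = inside & (prev > 0)
    return GrayImage(cropped, usable=inside)
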