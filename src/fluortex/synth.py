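"""Seeded synthetic autofluorescence-like scenes with ground truth.

Under blue-light excitation, healthy oral mucosa fluoresces brightly
with a smooth, low-contrast texture, while dysplastic tissue absorbs
the excitation and appears as darker regions with rougher local
texture.  The generator emulates exactly those two statistics — mean
intensity and local variance — because they are what the co-occurrence
features respond to:

* background: Gaussian-smoothed white noise rescaled to a chosen mean
  (default 180) and standard deviation, with a long correlation length
  (smooth, low adjacent-pixel contrast);
* lesions: darker (default mean 60), higher-variance (default 6x the
  background variance), shorter correlation length (high contrast);
* optionally, a device aperture: a bright circular rim with a
  near-black exterior, as left by a handheld visualization scope.

Lesion supports are disks anchored at super-pixel cell centers with
radius calibrated to the requested area fraction (and floored at
0.72x the cell side so the anchor cell is entirely lesion).  This
guarantees every scene contains at least one fully-anomalous
super-pixel, so per-image sensitivity is always defined — mirroring a
clinical set in which every image was included because it shows a
lesion large enough to biopsy.

Everything derives from a single seeded generator: the same spec
reproduces bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .device import CircleHit
from .imaging import GrayImage, LabelMask, save_image

__all__ = ["SceneSpec", "generate_scene", "generate_benchmark"]


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``leaf_size`` is the super-pixel side used to anchor lesion blobs;
    it matches the default quadtree leaf.  ``device_circle`` is
    ``(center_frac_row, center_frac_col, radius_frac)`` or ``None``.
    """

    seed: int
    size: int = 1792
    background_mean: float = 180.0
    background_sd: float = 10.0
    background_smoothness: float = 6.0  # pixels (Gaussian sigma)
    anomaly_mean: float = 60.0
    variance_multiplier: float = 6.0  # lesion local variance / background
    anomaly_smoothness: float = 1.0
    blob_count: int = 2
    area_fraction: float = 0.20
    leaf_size: int = 64
    device_circle: tuple[float, float, float] | None = None
    device_fill: int = 5
    rim_intensity: int = 235
    rim_thickness: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.area_fraction < 0.5):
            raise ValueError("area_fraction must lie in (0, 0.5)")
        if self.anomaly_mean >= self.background_mean:
            raise ValueError("lesions must be darker than background")
        if self.blob_count < 1 or self.size < 2 * self.leaf_size:
            raise ValueError("need at least 1 blob and >= 2 cells per side")


def _textured_field(
    rng: np.random.Generator, size: int, mean: float, sd: float, smoothness: float
) -> np.ndarray:
    """Smoothed white noise rescaled to exact mean/sd statistics."""
    field = gaussian_filter(rng.standard_normal((size, size)), smoothness)
    field = (field - field.mean()) / field.std()
    return mean + sd * field


def _blob_radius(spec: SceneSpec) -> float:
    """Disk radius hitting the target area fraction, floored so the
    anchor super-pixel cell (half-diagonal 0.71 x leaf) is fully covered."""
    target_area = spec.area_fraction * spec.size * spec.size
    radius = float(np.sqrt(target_area / (np.pi * spec.blob_count)))
    return max(radius, 0.72 * spec.leaf_size)


def _blob_mask(rng: np.random.Generator, spec: SceneSpec,
               usable_cells: np.ndarray) -> np.ndarray:
    """Union of disks anchored at randomly chosen super-pixel centers."""
    size, leaf = spec.size, spec.leaf_size
    radius = _blob_radius(spec)
    n = min(spec.blob_count, len(usable_cells))
    chosen = usable_cells[rng.choice(len(usable_cells), size=n, replace=False)]
    rr, cc = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    for gr, gc in chosen:
        cr = (gr + 0.5) * leaf
        ccol = (gc + 0.5) * leaf
        mask |= (rr - cr) ** 2 + (cc - ccol) ** 2 <= radius**2
    return mask


def generate_scene(
    spec: SceneSpec,
) -> tuple[GrayImage, LabelMask, CircleHit | None]:
    """Render one scene; returns image, ground-truth mask, and (when a
    device circle is planted) the true aperture as a :class:`CircleHit`."""
    rng = np.random.default_rng(spec.seed)
    size, leaf = spec.size, spec.leaf_size
    n_cells = size // leaf

    circle: CircleHit | None = None
    if spec.device_circle is not None:
        fr, fc, frad = spec.device_circle
        circle = CircleHit(
            int(round(fr * size)), int(round(fc * size)),
            int(round(frad * size)), 1.0,
        )

    # cells eligible to anchor a lesion: the whole blob disk must stay
    # inside the aperture when one is present
    blob_r = _blob_radius(spec)
    cells = []
    for gr in range(n_cells):
        for gc in range(n_cells):
            if circle is not None:
                cr, ccol = (gr + 0.5) * leaf, (gc + 0.5) * leaf
                dist = np.hypot(cr - circle.center_row, ccol - circle.center_col)
                if dist + blob_r > circle.radius:
                    continue
            cells.append((gr, gc))
    if not cells:
        raise ValueError("no super-pixel cell can host a lesion under this spec")

    background = _textured_field(
        rng, size, spec.background_mean, spec.background_sd, spec.background_smoothness
    )
    anomaly_sd = spec.background_sd * np.sqrt(spec.variance_multiplier)
    lesion = _textured_field(
        rng, size, spec.anomaly_mean, anomaly_sd, spec.anomaly_smoothness
    )
    mask = _blob_mask(rng, spec, np.asarray(cells))
    pixels = np.where(mask, lesion, background)

    if circle is not None:
        rr, cc = np.mgrid[0:size, 0:size]
        dist = np.sqrt((rr - circle.center_row) ** 2 + (cc - circle.center_col) ** 2)
        outside = dist > circle.radius
        pixels[outside] = spec.device_fill
        # bright rim just inside the aperture: the dominant edge (rim ->
        # near-black exterior) then lies exactly on the true radius
        rim = ~outside & (dist > circle.radius - spec.rim_thickness)
        pixels[rim] = spec.rim_intensity
        mask &= ~outside

    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    return GrayImage(pixels), LabelMask(mask.astype(np.uint8)), circle


def generate_benchmark(
    out_dir: str | Path,
    n_images: int = 10,
    n_groups: int = 2,
    seed: int = 0,
    size: int = 256,
    device_fraction: float = 0.0,
    **scene_overrides,
) -> pd.DataFrame:
    """Write a seeded benchmark dataset and return its manifest.

    Produces ``n_images`` PNG image/mask pairs split evenly into
    ``n_groups`` cross-validation groups, plus ``manifest.csv`` with
    columns image_path, mask_path, group_id, image_id.  With
    ``device_fraction > 0`` that share of images (the first of each
    block) gets a planted device aperture.  Fully reproducible: the same
    arguments regenerate identical files.
    """
    if n_images % n_groups != 0:
        raise ValueError(
            f"n_images={n_images} not divisible by n_groups={n_groups}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    per_group = n_images // n_groups
    n_device = int(round(device_fraction * n_images))

    records = []
    for i in range(n_images):
        device = (
            (0.5, 0.5, 0.42) if i < n_device else None
        )
        spec = SceneSpec(
            seed=int(child_seeds[i]), size=size, device_circle=device,
            **scene_overrides,
        )
        image, mask, _ = generate_scene(spec)
        image_path = out_dir / f"scene_{i:02d}.png"
        mask_path = out_dir / f"scene_{i:02d}_mask.png"
        save_image(image, image_path)
        save_image(mask.labels * 255, mask_path)
        records.append(
            {
                "image_path": image_path.name,
                "mask_path": mask_path.name,
                "group_id": i // per_group,
                "image_id": image_path.stem,
            }
        )
    manifest = pd.DataFrame(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    manifest = manifest.assign(
        image_path=[str(out_dir / p) for p in manifest["image_path"]],
        mask_path=[str(out_dir / p) for p in manifest["mask_path"]],
    )
    return manifest
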