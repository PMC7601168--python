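"""Image and mask I/O for autofluorescence screening.

Raster conventions used throughout the package: 8-bit intensities in
[0, 255], row 0 at the top, 0-based row-major indexing, and half-open
pixel windows ``[r0, r0+h) x [c0, c0+w)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "GrayImage",
    "LabelMask",
    "load_image",
    "load_mask",
    "save_image",
    "read_manifest",
    "rgb_to_gray",
    "LUMA_WEIGHTS",
]

#: Rec. 601 luma weights used for RGB -> grayscale reduction.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class GrayImage:
    """Single-channel 8-bit image.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (height, width)
        Intensity raster.
    usable : ndarray of bool, optional
        Per-pixel flag marking pixels that belong to the imaged tissue
        area.  ``None`` means the whole frame is usable.  Device removal
        sets this to the interior of the detected aperture so that
        downstream windowing can exclude the artificial black exterior.
    """

    pixels: np.ndarray
    usable: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixels.dtype != np.uint8:
            arr = np.asarray(self.pixels)
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)
        if self.usable is not None:
            self.usable = np.asarray(self.usable, dtype=bool)
            if self.usable.shape != self.pixels.shape:
                raise ValueError("usable mask shape must match pixels")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Binary ground-truth mask: 1 = anomalous tissue, 0 = standard."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        self.labels = (self.labels != 0).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Reduce an 8-bit RGB array to one channel with Rec. 601 weights.

    The weighted sum is rounded to the nearest integer, so equal-channel
    inputs map to themselves and the map is monotone in each channel.
    """
    w = np.asarray(LUMA_WEIGHTS)
    gray = np.tensordot(rgb[..., :3].astype(np.float64), w, axes=([-1], [0]))
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def load_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF image, converting RGB to grayscale.

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded.
    ValueError
        If the raster is not 8-bit.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit raster, got {arr.dtype}")
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"{path}: unsupported channel count {arr.shape[2]}")
        arr = rgb_to_gray(arr)
    elif arr.ndim != 2:
        raise ValueError(f"{path}: unsupported raster dimensionality {arr.ndim}")
    return GrayImage(arr)


def load_mask(path: str | Path, image: GrayImage) -> LabelMask:
    """Read a ground-truth mask and check its geometry against *image*.

    Any nonzero mask pixel is treated as anomalous so that both 1-valued
    and 255-valued mask files are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such mask file: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:  # tolerate RGB-saved masks
        arr = arr[..., :3].max(axis=-1)
    if arr.shape != image.shape:
        raise ValueError(
            f"mask shape {arr.shape} does not match image shape {image.shape}"
        )
    return LabelMask(arr)


def save_image(image: GrayImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF (lossless round-trip for PNG)."""
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a batch manifest CSV with columns image_path, mask_path, group_id.

    Relative paths are resolved against the manifest's directory.  An
    ``image_id`` column is added from the image file stem when absent.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"image_path", "mask_path", "group_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    base = path.parent
    for col in ("image_path", "mask_path"):
        df[col] = [str(base / p) if not Path(p).is_absolute() else p for p in df[col]]
    if "image_id" not in df.columns:
        df["image_id"] = [Path(p).stem for p in df["image_path"]]
    return df
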