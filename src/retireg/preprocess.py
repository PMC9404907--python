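"""Loading fundus photographs and bringing them to the working resolution.

The registration network operates on square rasters whose side is a
multiple of 4 (two exact pooling halvings). Production scale is 512x512;
the identical code path runs at any smaller size for testing.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .images import FundusImage

__all__ = [
    "load_fundus",
    "save_png",
    "to_working_resolution",
    "extract_structure_channel",
]


def load_fundus(path: str | os.PathLike) -> FundusImage:
    """Read a PNG/TIFF/JPEG raster and rescale intensities to [0, 1].

    Integer images are divided by the maximum of their bit depth (255 for
    8-bit, 65535 for 16-bit); float images are assumed to already be on
    [0, 1]. An alpha channel, if present, is dropped.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # decoder-specific exception zoo
        raise ValueError(f"could not decode image {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        pixels = arr.astype(float) / scale
    else:
        pixels = np.clip(arr.astype(float), 0.0, 1.0)
    return FundusImage(pixels=pixels, source_path=str(path))


def save_png(img: FundusImage | np.ndarray, path: str | os.PathLike, bits: int = 8) -> None:
    """Write an image (or bare array in [0, 1]) as an 8- or 16-bit PNG."""
    pixels = img.pixels if isinstance(img, FundusImage) else np.asarray(img, dtype=float)
    if bits == 8:
        out = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)
    elif bits == 16:
        out = np.round(np.clip(pixels, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    iio.imwrite(path, out)


def to_working_resolution(img: FundusImage, size: int = 512) -> FundusImage:
    """Resize to ``size x size`` with bilinear interpolation.

    Non-square inputs are stretched anisotropically: all downstream shapes
    assume a square raster. ``size`` must be a positive multiple of 4 so
    the network's two pooling halvings are exact. Resizing an image that
    is already at the target size returns it unchanged.
    """
    if size <= 0 or size % 4 != 0:
        raise ValueError(f"working size must be a positive multiple of 4, got {size}")
    if img.height == size and img.width == size:
        return img
    shape = (size, size) if not img.is_rgb else (size, size, img.pixels.shape[2])
    down = size < min(img.height, img.width)
    out = _sk_resize(img.pixels, shape, order=1, anti_aliasing=down, preserve_range=True)
    return FundusImage(pixels=np.clip(out, 0.0, 1.0), source_path=img.source_path)


def extract_structure_channel(img: FundusImage) -> np.ndarray:
    """Return the 2-D grayscale plane the vessel segmentation consumes.

    For RGB fundus photographs the green channel is used: blood vessels
    show the highest contrast against the retinal background there, which
    is standard practice in fundus image analysis. Grayscale input is
    returned as-is.
    """
    if img.is_rgb:
        return np.ascontiguousarray(img.pixels[:, :, 1])
    return img.pixels
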