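"""Core raster containers: fundus photographs and vessel/structure maps.

All pixel data are stored as floating-point intensities on the [0, 1]
scale; every formula in the package (NCC, SSIM with dynamic range L = 1,
MSE) operates on this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FundusImage", "VesselMap"]


@dataclass
class FundusImage:
    """A 2-D fundus photograph with intensities in [0, 1].

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array, float in [0, 1].
    source_path : str, optional
        Where the raster was loaded from, if anywhere.
    """

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-channel image, got shape {px.shape}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ValueError(f"color images must have 3 channels, got {px.shape[2]}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image too small: {px.shape[0]}x{px.shape[1]} (need >= 8x8)")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


@dataclass
class VesselMap:
    """Segmented vessel/structure image: soft response plus a binary view.

    The soft map (values in [0, 1]) is what the network and the NCC
    objective consume; the binary view is what Dice, the gain coefficient
    and connected-component filtering operate on.
    """

    soft: np.ndarray
    binary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        soft = np.asarray(self.soft, dtype=float)
        if soft.ndim != 2:
            raise ValueError(f"vessel map must be 2-D, got shape {soft.shape}")
        if soft.size and (soft.min() < -1e-9 or soft.max() > 1 + 1e-9):
            raise ValueError("soft map values must lie in [0, 1]")
        self.soft = np.clip(soft, 0.0, 1.0)
        if self.binary is None:
            self.binary = self.soft >= 0.5
        else:
            b = np.asarray(self.binary)
            if b.shape != self.soft.shape:
                raise ValueError("binary view shape must match soft map")
            if b.dtype != bool:
                vals = np.unique(b)
                if not np.all(np.isin(vals, (0, 1))):
                    raise ValueError("binary view must contain only {0, 1}")
            self.binary = b.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.soft.shape  # type: ignore[return-value]
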