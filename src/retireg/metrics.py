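"""Registration quality metrics: MSE, SSIM, Dice and gain coefficient.

All four are evaluated on vessel maps (the B images): MSE and SSIM on
the soft maps (they are image-similarity measures), Dice and the gain
coefficient on the binary views, which share one binarization so the
two overlap numbers describe the same pixel sets.

Dice is the standard overlap 2|A∩B| / (|A| + |B|), which lives in
[0, 1] with 1 at perfect overlap. The gain coefficient compares the
reference overlap after registration against before:
GC = |B_ref ∩ B_warp| / |B_ref ∩ B_mov|; values above 1 mean the warp
increased alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

from .images import VesselMap

__all__ = ["SSIMParams", "MetricReport", "mse", "ssim", "dice",
           "gain_coefficient", "evaluate_all"]


@dataclass(frozen=True)
class SSIMParams:
    """SSIM stabilizers and window settings.

    ``c1 = (K1 L)^2`` and ``c2 = (K2 L)^2`` with K1 = 0.01, K2 = 0.03 and
    dynamic range L = 1 (intensities live on [0, 1]). Windowed mode uses
    an 11x11 Gaussian window with sigma 1.5; global mode evaluates the
    SSIM expression once over the whole image.
    """

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0
    window_size: int = 11
    sigma: float = 1.5
    mode: str = "windowed"  # "windowed" | "global"

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


@dataclass
class MetricReport:
    """The four quality scores for one registered pair."""

    mse: float
    ssim: float
    dice: float
    gc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _as_soft(x: VesselMap | np.ndarray) -> np.ndarray:
    return x.soft if isinstance(x, VesselMap) else np.asarray(x, dtype=float)


def _as_mask(x: VesselMap | np.ndarray) -> np.ndarray:
    if isinstance(x, VesselMap):
        return x.binary
    arr = np.asarray(x)
    return arr.astype(bool) if arr.dtype == bool else np.asarray(arr, dtype=float) >= 0.5


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(b_ref: VesselMap | np.ndarray, b_warp: VesselMap | np.ndarray) -> float:
    """Mean squared error (1/(H W)) sum (B_ref - B_warp)^2."""
    r, w = _as_soft(b_ref), _as_soft(b_warp)
    _check_shapes(r, w)
    return float(np.mean((r - w) ** 2))


def ssim(b_ref: VesselMap | np.ndarray, b_warp: VesselMap | np.ndarray,
         params: SSIMParams = SSIMParams()) -> float:
    """Structural similarity between two images on the [0, 1] scale.

    Windowed mode (default) averages the SSIM expression over Gaussian
    windows (size 11, sigma 1.5, population covariances); global mode
    evaluates it once from whole-image statistics. Values can drop below
    0 for anti-correlated images and are reported as-is.
    """
    r, w = _as_soft(b_ref), _as_soft(b_warp)
    _check_shapes(r, w)
    if params.mode == "global":
        mu_r, mu_w = r.mean(), w.mean()
        var_r, var_w = r.var(), w.var()
        cov = ((r - mu_r) * (w - mu_w)).mean()
        num = (2 * mu_r * mu_w + params.c1) * (2 * cov + params.c2)
        den = (mu_r**2 + mu_w**2 + params.c1) * (var_r + var_w + params.c2)
        return float(num / den)
    if params.mode != "windowed":
        raise ValueError(f"unknown SSIM mode {params.mode!r}")
    return float(_sk_ssim(
        r, w,
        data_range=params.dynamic_range,
        gaussian_weights=True,
        sigma=params.sigma,
        win_size=params.window_size,
        use_sample_covariance=False,
        K1=params.k1,
        K2=params.k2,
    ))


def dice(b_ref: VesselMap | np.ndarray, b_warp: VesselMap | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of the binary views.

    Two empty masks agree perfectly and score 1.0.
    """
    a, b = _as_mask(b_ref), _as_mask(b_warp)
    _check_shapes(a, b)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def gain_coefficient(b_ref: VesselMap | np.ndarray, b_mov: VesselMap | np.ndarray,
                     b_warp: VesselMap | np.ndarray) -> float:
    """Overlap gain |B_ref ∩ B_warp| / |B_ref ∩ B_mov|.

    Equals 1 when the warp leaves the reference overlap unchanged;
    larger values mean more aligned pixels than before registration.
    Undefined (raises) when the pre-registration overlap is empty.
    """
    ref, mov, warp = _as_mask(b_ref), _as_mask(b_mov), _as_mask(b_warp)
    _check_shapes(ref, mov)
    _check_shapes(ref, warp)
    baseline = int((ref & mov).sum())
    if baseline == 0:
        raise ZeroDivisionError("gain coefficient undefined: empty B_ref ∩ B_mov baseline")
    return int((ref & warp).sum()) / baseline


def evaluate_all(b_ref: VesselMap | np.ndarray, b_mov: VesselMap | np.ndarray,
                 b_warp: VesselMap | np.ndarray,
                 ssim_params: SSIMParams = SSIMParams()) -> MetricReport:
    """Combined report: MSE/SSIM on soft maps, Dice/GC on binary views."""
    return MetricReport(
        mse=mse(_as_soft(b_ref), _as_soft(b_warp)),
        ssim=ssim(_as_soft(b_ref), _as_soft(b_warp), ssim_params),
        dice=dice(_as_mask(b_ref), _as_mask(b_warp)),
        gc=gain_coefficient(_as_mask(b_ref), _as_mask(b_mov), _as_mask(b_warp)),
    )
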