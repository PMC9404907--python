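"""Normalized cross-correlation objective.

The similarity between the warped and reference vessel maps is the
global zero-mean normalized cross-correlation

    NCC(T, R) = sum(T.R) / sqrt(sum(T^2) sum(R^2)),

with T and R the mean-subtracted warped and reference images, evaluated
over the full (fully overlapping) image domain. Zero-meaning both
operands makes the score a true correlation in [-1, 1], invariant to
positive affine intensity changes of either image. Training minimizes
``-NCC`` (i.e., maximizes the fitness).
"""

from __future__ import annotations

import numpy as np

from .images import VesselMap

__all__ = ["ncc", "loss", "ConstantImageError"]


class ConstantImageError(ValueError):
    """Correlation undefined: an operand has zero intensity variance."""


def _as_array(x: VesselMap | np.ndarray) -> np.ndarray:
    return x.soft if isinstance(x, VesselMap) else np.asarray(x, dtype=float)


def ncc(warped: VesselMap | np.ndarray, ref: VesselMap | np.ndarray) -> float:
    """Global zero-mean NCC between two equally shaped images, in [-1, 1]."""
    t, r = _as_array(warped), _as_array(ref)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {r.shape}")
    t = t - t.mean()
    r = r - r.mean()
    denom = np.sqrt((t * t).sum() * (r * r).sum())
    if denom == 0.0:
        raise ConstantImageError("NCC undefined for constant images (zero denominator)")
    return float(np.clip((t * r).sum() / denom, -1.0, 1.0))


def loss(warped: VesselMap | np.ndarray, ref: VesselMap | np.ndarray) -> float:
    """Training loss: negated NCC (minimizing it maximizes the fitness)."""
    return -ncc(warped, ref)


def ncc_batch_with_grad(warped: np.ndarray, ref: np.ndarray):
    """Per-sample NCC over a batch and its gradient w.r.t. ``warped``.

    Parameters
    ----------
    warped, ref : ndarray
        Stacks of shape (N, H, W).

    Returns
    -------
    scores : ndarray, shape (N,)
    grad : ndarray, shape (N, H, W)
        d scores[n] / d warped[n], per sample (not summed with any loss
        sign; callers negate for the fitness-maximizing loss).
    """
    n = warped.shape[0]
    t = warped - warped.mean(axis=(1, 2), keepdims=True)
    r = ref - ref.mean(axis=(1, 2), keepdims=True)
    tt = (t * t).sum(axis=(1, 2))
    rr = (r * r).sum(axis=(1, 2))
    tr = (t * r).sum(axis=(1, 2))
    denom = np.sqrt(tt * rr)
    if np.any(denom == 0.0):
        raise ConstantImageError("NCC undefined for constant images (zero denominator)")
    scores = tr / denom
    # d ncc / d t = r / denom - (tr / tt) * t / denom ; then project out the
    # mean direction (centering has zero net gradient since r is zero-mean,
    # but the tt-term needs it with t not exactly zero-mean numerically)
    g = (r - (tr / tt)[:, None, None] * t) / denom[:, None, None]
    g -= g.mean(axis=(1, 2), keepdims=True)
    return scores, g
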