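"""Unsupervised training of the registration model.

Each step stacks (B_ref, B_mov) pairs, predicts displacement fields,
warps the moving soft maps through the differentiable bilinear sampler,
scores them against the references with NCC, and follows the ADAM update
on ``-mean(NCC)``. No labels, landmarks or ground-truth deformations
enter the loop; the mean per-epoch NCC is recorded as the learning
curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corrnet import RegistrationModel, forward_grid, save_checkpoint
from .images import FundusImage, VesselMap
from .nn.adam import Adam
from .objective import ncc_batch_with_grad
from .preprocess import extract_structure_channel, to_working_resolution
from .stn import identity_grid, sample_bilinear_batch, warp_vessel_map
from .vesselseg import segment_vessels

__all__ = ["TrainingConfig", "TrainingDivergenceError", "train", "register_pair"]


@dataclass
class TrainingConfig:
    """Optimization settings for the unsupervised loop.

    Production defaults: batches of 8 pairs for 5000 epochs, ADAM with
    betas (0.9, 0.999). The learning rate defaults to 1e-4, which keeps
    displacement-field updates stable.
    """

    epochs: int = 5000
    batch_size: int = 8
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    checkpoint_every: int = 0  # 0 = no intermediate checkpoints
    checkpoint_path: str | None = None
    smoothness_weight: float = 0.0  # optional extension, off by default
    log_every: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class TrainingDivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


def _pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    refs, movs = [], []
    for b_ref, b_mov in pairs:
        r = b_ref.soft if isinstance(b_ref, VesselMap) else np.asarray(b_ref, dtype=float)
        m = b_mov.soft if isinstance(b_mov, VesselMap) else np.asarray(b_mov, dtype=float)
        if r.shape != m.shape:
            raise ValueError("pair members must share a shape")
        refs.append(r)
        movs.append(m)
    return np.stack(refs), np.stack(movs)


def _smoothness_penalty_grad(disp: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared forward difference of the field and its gradient."""
    dr = np.diff(disp, axis=1)
    dc = np.diff(disp, axis=2)
    n = disp[0].size
    value = float((dr**2).sum() + (dc**2).sum()) / (disp.shape[0] * n)
    g = np.zeros_like(disp)
    g[:, :-1] -= 2 * dr
    g[:, 1:] += 2 * dr
    g[:, :, :-1] -= 2 * dc
    g[:, :, 1:] += 2 * dc
    return value, g / (disp.shape[0] * n)


def train(model: RegistrationModel, pairs, config: TrainingConfig):
    """Optimize ``model`` on (B_ref, B_mov) vessel-map pairs.

    Returns ``(model, learning_curve)`` where the curve holds the mean
    NCC fitness per epoch. Deterministic given ``config.seed`` (shuffling
    and all arithmetic are seeded/sequenced identically across runs).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("training requires a non-empty set of pairs")
    refs, movs = _pair_arrays(pairs)
    size = model.config.input_size
    if refs.shape[1] != size or refs.shape[2] != size:
        raise ValueError(f"pairs must be at model input_size {size}, got {refs.shape[1:]}")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.layers, learning_rate=config.learning_rate,
                     beta1=config.beta1, beta2=config.beta2)
    ident = identity_grid(size, size)[None]
    curve: list[float] = []
    n = len(pairs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_scores: list[np.ndarray] = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x = np.stack([np.stack([refs[i], movs[i]], axis=-1) for i in idx])
            disp = model.forward(x, training=True)
            grids = ident + disp
            warped, warp_grad = sample_bilinear_batch(movs[idx], grids)
            scores, dscore_dwarp = ncc_batch_with_grad(warped, refs[idx])
            if not np.all(np.isfinite(scores)):
                raise TrainingDivergenceError(epoch)
            # loss = -mean(scores); gradient scaled per sample
            g_warp = -dscore_dwarp / len(idx)
            g_disp = warp_grad(g_warp)
            if config.smoothness_weight > 0.0:
                _, g_pen = _smoothness_penalty_grad(disp)
                g_disp = g_disp + config.smoothness_weight * g_pen
            model.backward(g_disp)
            optimizer.step()
            epoch_scores.append(scores)
        mean_fitness = float(np.concatenate(epoch_scores).mean())
        if not np.isfinite(mean_fitness):
            raise TrainingDivergenceError(epoch)
        curve.append(mean_fitness)
        if config.log_every and (epoch + 1) % config.log_every == 0:
            print(f"epoch {epoch + 1}/{config.epochs}  mean NCC {mean_fitness:.4f}")
        if (config.checkpoint_every and config.checkpoint_path
                and (epoch + 1) % config.checkpoint_every == 0):
            model.training_curve = curve
            save_checkpoint(model, config.checkpoint_path)
    model.training_curve = curve
    return model, curve


def register_pair(model: RegistrationModel, i_ref: FundusImage, i_mov: FundusImage,
                  **segment_kwargs):
    """One-shot registration of a raw fundus image pair.

    Runs the full inference path — working-resolution resize, structure
    channel extraction, IUWT vessel segmentation, correspondence-grid
    prediction, bilinear warp — with no per-pair optimization. Returns
    ``(b_warp, displacement)``.
    """
    size = model.config.input_size
    b_ref = segment_vessels(extract_structure_channel(to_working_resolution(i_ref, size)),
                            **segment_kwargs)
    b_mov = segment_vessels(extract_structure_channel(to_working_resolution(i_mov, size)),
                            **segment_kwargs)
    disp = forward_grid(model, b_ref, b_mov)
    return warp_vessel_map(b_mov, disp), disp
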