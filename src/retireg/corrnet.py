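"""U-shaped correspondence-grid network.

Maps a stacked pair of vessel maps (reference, moving) to a dense
per-pixel displacement field. Architecture: an input block of two 3x3
convolutions, ``depth`` downsampling blocks (2x2 max pool + two
convolutions, doubling the filter count), ``depth`` upsampling blocks
(2x2 stride-2 transposed convolution halving the filter count, skip
concatenation with the encoder block at the same level, two
convolutions), and a final 1x1 convolution with 2 output channels and no
activation. Every other convolution carries ReLU + batch normalization.

The output is read as a displacement in pixel units added to the
identity grid. The final layer is zero-initialized so a fresh model
starts exactly at the identity transform, a stable training start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .images import VesselMap
from .nn.layers import BatchNorm2d, Conv2d, ConvTranspose2x2, MaxPool2x2, ReLU

__all__ = ["NetworkConfig", "RegistrationModel", "build_model", "forward_grid",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the correspondence network.

    ``base_filters`` is the filter count of the input block (doubling at
    every downsampling level), ``depth`` the number of pool/unpool
    levels, ``input_size`` the square working resolution.
    """

    base_filters: int = 16
    depth: int = 2
    kernel_size: int = 3
    input_size: int = 512

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )


class _ConvBNRelu:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.conv = Conv2d(c_in, c_out, k, rng)
        self.bn = BatchNorm2d(c_out)
        self.relu = ReLU()

    def forward(self, x, training):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training), training)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.relu.backward(g)))

    @property
    def layers(self):
        return [self.conv, self.bn]


class RegistrationModel:
    """Trainable correspondence-grid network (weights + config)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.training_curve: list[float] = []
        rng = np.random.default_rng(seed)
        f, k, d = config.base_filters, config.kernel_size, config.depth

        def block(c_in, c_out):
            return [_ConvBNRelu(c_in, c_out, k, rng), _ConvBNRelu(c_out, c_out, k, rng)]

        self.enc_blocks = [block(2, f)]
        for lv in range(1, d + 1):
            self.enc_blocks.append(block(f * 2 ** (lv - 1), f * 2**lv))
        self.pools = [MaxPool2x2() for _ in range(d)]
        self.deconvs = []
        self.dec_blocks = []
        for lv in range(d, 0, -1):
            c_hi, c_lo = f * 2**lv, f * 2 ** (lv - 1)
            self.deconvs.append(ConvTranspose2x2(c_hi, c_lo, rng))
            self.dec_blocks.append(block(2 * c_lo, c_lo))
        self.head = Conv2d(f, 2, kernel_size=1, zero_init=True)

    # -- plumbing ------------------------------------------------------
    @property
    def layers(self):
        out = []
        for blk in self.enc_blocks:
            for u in blk:
                out.extend(u.layers)
        out.extend(self.pools)
        for dc, blk in zip(self.deconvs, self.dec_blocks):
            out.append(dc)
            for u in blk:
                out.extend(u.layers)
        out.append(self.head)
        return out

    def parameter_count(self) -> int:
        return sum(p.size for ly in self.layers for p in ly.params.values())

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Input (N, H, W, 2) pair stack -> displacement fields (N, H, W, 2)."""
        if x.ndim != 4 or x.shape[3] != 2:
            raise ValueError(f"expected (N, H, W, 2) input, got {x.shape}")
        if x.shape[1] % 2**self.config.depth or x.shape[2] % 2**self.config.depth:
            raise ValueError("spatial size must be divisible by 2^depth")
        skips = []
        h = x
        for lv, blk in enumerate(self.enc_blocks):
            if lv > 0:
                h = self.pools[lv - 1].forward(h, training)
            for u in blk:
                h = u.forward(h, training)
            skips.append(h)
        self._skip_channels = []
        for dc, blk, skip in zip(self.deconvs, self.dec_blocks, reversed(skips[:-1])):
            up = dc.forward(h, training)
            self._skip_channels.append(up.shape[3])
            h = np.concatenate([up, skip], axis=3)
            for u in blk:
                h = u.forward(h, training)
        return self.head.forward(h, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Push gradients back through the cached forward pass.

        Returns the gradient w.r.t. the network input (N, H, W, 2).
        """
        g = self.head.backward(grad)
        skip_grads = []
        for dc, blk, c_up in zip(reversed(self.deconvs), reversed(self.dec_blocks),
                                 reversed(self._skip_channels)):
            for u in reversed(blk):
                g = u.backward(g)
            skip_grads.append(g[..., c_up:])
            g = dc.backward(g[..., :c_up])
        # decoder stages were unwound bottom-up, so skip_grads[lv] is the
        # gradient reaching encoder level lv through its skip connection
        for lv in range(len(self.enc_blocks) - 1, -1, -1):
            if lv < len(skip_grads):
                g = g + skip_grads[lv]
            for u in reversed(self.enc_blocks[lv]):
                g = u.backward(g)
            if lv > 0:
                g = self.pools[lv - 1].backward(g)
        return g


def build_model(config: NetworkConfig, seed: int = 0) -> RegistrationModel:
    """Construct a correspondence network with seed-deterministic weights."""
    return RegistrationModel(config, seed=seed)


def _stack_pair(b_ref: VesselMap | np.ndarray, b_mov: VesselMap | np.ndarray) -> np.ndarray:
    r = b_ref.soft if isinstance(b_ref, VesselMap) else np.asarray(b_ref, dtype=float)
    m = b_mov.soft if isinstance(b_mov, VesselMap) else np.asarray(b_mov, dtype=float)
    if r.shape != m.shape:
        raise ValueError(f"reference/moving shapes differ: {r.shape} vs {m.shape}")
    return np.stack([r, m], axis=-1)[None]


def forward_grid(model: RegistrationModel, b_ref: VesselMap | np.ndarray,
                 b_mov: VesselMap | np.ndarray) -> np.ndarray:
    """One-shot displacement field for a (reference, moving) vessel-map pair.

    Returns an ``(H, W, 2)`` array of (d_row, d_col) pixel displacements
    to be added to the identity grid. Deterministic given weights and
    inputs (inference mode: batch-norm running averages).
    """
    x = _stack_pair(b_ref, b_mov)
    if x.shape[1] != model.config.input_size or x.shape[2] != model.config.input_size:
        raise ValueError(
            f"input size {x.shape[1]}x{x.shape[2]} does not match model "
            f"input_size {model.config.input_size}"
        )
    return model.forward(x, training=False)[0]


# -- checkpointing -----------------------------------------------------


def save_checkpoint(model: RegistrationModel, path: str) -> None:
    """Write config + all weights and batch-norm statistics to one .npz."""
    arrays = {"__config__": np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)}
    arrays["__curve__"] = np.asarray(model.training_curve, dtype=float)
    for i, ly in enumerate(model.layers):
        for k, v in ly.params.items():
            arrays[f"layer{i}:{k}"] = v
        if isinstance(ly, BatchNorm2d):
            arrays[f"layer{i}:running_mean"] = ly.running_mean
            arrays[f"layer{i}:running_var"] = ly.running_var
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> RegistrationModel:
    """Bit-exact inverse of :func:`save_checkpoint`."""
    data = np.load(path)
    config = NetworkConfig(**json.loads(bytes(data["__config__"]).decode()))
    model = RegistrationModel(config, seed=0)
    model.training_curve = list(data["__curve__"])
    for i, ly in enumerate(model.layers):
        for k in ly.params:
            ly.params[k] = data[f"layer{i}:{k}"].copy()
        if isinstance(ly, BatchNorm2d):
            ly.running_mean = data[f"layer{i}:running_mean"].copy()
            ly.running_var = data[f"layer{i}:running_var"].copy()
    return model
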