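"""Minimal NumPy neural-network layers with hand-written gradients.

Only what the correspondence-grid network needs: 'same' 3x3 (and 1x1)
convolution, batch normalization, ReLU, 2x2 max pooling and a 2x2
stride-2 transposed convolution. Data layout is NHWC throughout;
convolutions are evaluated as im2col + matmul so the heavy lifting is a
single BLAS call per layer.

Each layer exposes ``forward(x, training)`` and ``backward(grad)``;
``backward`` consumes the cache left by the immediately preceding
forward call and fills per-parameter ``.grads``. Parameters live in
``.params`` (dict name -> ndarray) so the optimizer and checkpointing
can treat all layers uniformly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "MaxPool2x2", "ConvTranspose2x2"]


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """'Same' convolution, stride 1, odd square kernel, zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = kernel_size
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel_size * kernel_size
        if zero_init:
            w = np.zeros((kernel_size, kernel_size, c_in, c_out))
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init")
            w = _he_init(rng, (kernel_size, kernel_size, c_in, c_out), fan_in)
        self.params = {"w": w, "b": np.zeros(c_out)}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (N, H, W, C, k, k) -> (N*H*W, k*k*C) with (k, k, C) ordering
        n, h, w = x.shape[:3]
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, k * k * self.c_in)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = self._im2col(x)
        wmat = self.params["w"].reshape(-1, self.c_out)
        out = cols @ wmat + self.params["b"]
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, h, w, _ = xshape
        g = grad.reshape(n * h * w, self.c_out)
        self.grads["w"] = (cols.T @ g).reshape(self.params["w"].shape)
        self.grads["b"] = g.sum(axis=0)
        # grad w.r.t. input = 'same' convolution of grad with spatially
        # flipped kernels, channels transposed
        w_flip = self.params["w"][::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,c_out,c_in)
        back = Conv2d.__new__(Conv2d)
        back.k, back.c_in, back.c_out = self.k, self.c_out, self.c_in
        back.params = {"w": w_flip, "b": np.zeros(self.c_in)}
        back.grads = {}
        return back.forward(grad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W).

    Batch statistics during training; exponential running averages
    (momentum 0.9) at inference.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, x.shape, training)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape, training = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.grads["gamma"] = (grad * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = grad.sum(axis=(0, 1, 2))
        g = grad * self.params["gamma"]
        if not training:
            return g * inv_std
        return (inv_std / m) * (
            m * g - g.sum(axis=(0, 1, 2)) - xhat * (g * xhat).sum(axis=(0, 1, 2))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pool requires even spatial dimensions")
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(n, h // 2, w // 2, 4, c)
        self._argmax = win.argmax(axis=3)
        self._xshape = x.shape
        return np.take_along_axis(win, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        out = np.zeros((n, h // 2, w // 2, 4, c))
        np.put_along_axis(out, self._argmax[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        out = out.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return out.reshape(n, h, w, c)


class ConvTranspose2x2(Layer):
    """Transposed convolution, 2x2 kernel, stride 2 (exact spatial doubling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "w": _he_init(rng, (c_in, c_out, 2, 2), c_in),
            "b": np.zeros(c_out),
        }

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        self._xshape = x.shape
        self._x = x
        wmat = self.params["w"].reshape(self.c_in, self.c_out * 4)
        out = (x.reshape(-1, self.c_in) @ wmat).reshape(n, h, w, self.c_out, 2, 2)
        out = out.transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * h, 2 * w, self.c_out)
        return out + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._xshape
        g = grad.reshape(n, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 5, 2, 4)
        g = g.reshape(-1, self.c_out * 4)  # rows align with x pixels
        wmat = self.params["w"].reshape(self.c_in, self.c_out * 4)
        self.grads["w"] = (self._x.reshape(-1, self.c_in).T @ g).reshape(self.params["w"].shape)
        self.grads["b"] = grad.sum(axis=(0, 1, 2))
        return (g @ wmat.T).reshape(n, h, w, self.c_in)
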