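"""Minimal 3D neural-network layers on numpy arrays.

Tensors are (N, C, D, H, W).  Each layer caches what its backward pass
needs; ``backward`` consumes the loss gradient w.r.t. its output and
returns the gradient w.r.t. its input, accumulating parameter gradients
in ``.grads``.  Deterministic given the seeding of the initializers.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv3d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 3D cross-correlation. x: (N,C,D,H,W), w: (O,C,k,k,k)."""
    k = w.shape[-1]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    # win: (N, C, D', H', W', k, k, k)
    return np.einsum("ncdhwijk,ocijk->nodhw", win, w, optimize=True)


class Layer:
    params: Dict[str, np.ndarray]
    grads: Dict[str, np.ndarray]

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """k x k x k padded convolution, stride 1, He-normal init."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.pad = k // 2
        fan_in = c_in * k ** 3
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      (c_out, c_in, k, k, k))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train=True):
        self._x = x
        out = _conv3d(x, self.params["w"], self.pad)
        return out + self.params["b"][None, :, None, None, None]

    def backward(self, dout):
        x, w, k, pad = self._x, self.params["w"], self.k, self.pad
        self.grads["b"] = dout.sum(axis=(0, 2, 3, 4))
        xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        self.grads["w"] = np.einsum("nodhw,ncdhwijk->ocijk", dout, win,
                                    optimize=True)
        # dx: full correlation of dout with the spatially flipped kernel
        w_flip = w[:, :, ::-1, ::-1, ::-1].swapaxes(0, 1)  # (C, O, k, k, k)
        dx = _conv3d(np.pad(dout, ((0, 0), (0, 0)) + ((k - 1 - pad,) * 2,) * 3),
                     w_flip, pad=0)
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class BatchNorm3d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=True):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        shp = (1, -1, 1, 1, 1)
        self._std = np.sqrt(var + self.eps).reshape(shp)
        self._xhat = (x - mean.reshape(shp)) / self._std
        self._m = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
        return self.params["gamma"].reshape(shp) * self._xhat \
            + self.params["beta"].reshape(shp)

    def backward(self, dout):
        shp = (1, -1, 1, 1, 1)
        axes = (0, 2, 3, 4)
        xhat, std, m = self._xhat, self._std, self._m
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"].reshape(shp)
        return (dxhat - dxhat.mean(axis=axes).reshape(shp)
                - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp)) / std


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, train=True):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2x2 pooling")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // 2, h // 2, w // 2, 8)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, d, h, w = self._shape
        dxr = np.zeros((n, c, d // 2, h // 2, w // 2, 8))
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return dxr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)


class ConvTranspose3d(Layer):
    """2x2x2 transposed convolution, stride 2 (doubles spatial size)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * 8
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      (c_in, c_out, 2, 2, 2))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train=True):
        self._x = x
        n, c, d, h, w = x.shape
        out = np.einsum("ncdhw,coijk->nodihjwk", x, self.params["w"],
                        optimize=True)
        out = out.reshape(n, -1, 2 * d, 2 * h, 2 * w)
        return out + self.params["b"][None, :, None, None, None]

    def backward(self, dout):
        x = self._x
        n, c, d, h, w = x.shape
        o = dout.shape[1]
        dr = dout.reshape(n, o, d, 2, h, 2, w, 2)
        self.grads["b"] = dout.sum(axis=(0, 2, 3, 4))
        self.grads["w"] = np.einsum("ncdhw,nodihjwk->coijk", x, dr,
                                    optimize=True)
        return np.einsum("nodihjwk,coijk->ncdhw", dr, self.params["w"],
                         optimize=True)


class Concat(Layer):
    """Channel concatenation of a skip tensor with the upsampled tensor."""

    def forward_pair(self, skip: np.ndarray, up: np.ndarray) -> np.ndarray:
        self._c_skip = skip.shape[1]
        return np.concatenate([skip, up], axis=1)

    def backward(self, dout):
        return dout[:, : self._c_skip], dout[:, self._c_skip:]


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers: List[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = self.beta1 * self.m[li][k] + (1 - self.beta1) * g
                self.v[li][k] = self.beta2 * self.v[li][k] + (1 - self.beta2) * g * g
                mhat = self.m[li][k] / b1t
                vhat = self.v[li][k] / b2t
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
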