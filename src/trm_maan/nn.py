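"""Neural-network layers and an Adam optimizer on top of :mod:`autodiff`.

Convolutions are dedicated primitives (shift-and-add loops over the kernel
taps in both directions) rather than compositions of elementary ops or
im2col expansions: they dominate runtime and the tap loop avoids
materializing window tensors.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "Parameter", "Linear", "Conv1d", "Conv2d", "DepthwiseConv2d",
    "LayerNorm", "BatchNorm2d", "MaxPool2d", "ModuleList", "gradient_reversal", "softmax",
    "log_softmax", "Adam", "clip_gradients_",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    """Lightweight container tracking parameters and submodules by attribute."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("parameter name mismatch when loading state")
        for n, p in own.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for parameter {n!r}")
            p.data[...] = state[n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def _conv1d_primitive(x: Tensor, weight: Tensor, bias: Tensor,
                      stride: int, pad: tuple[int, int]) -> Tensor:
    """x: [B, C, L]; weight: [D, C, k]; returns [B, D, L_out].

    Implemented as a shift-and-add loop over the k kernel taps: each tap is a
    [C -> D] matmul over a strided slice, which avoids materializing the
    im2col window tensor.
    """
    B, C, L = x.data.shape
    D, _, k = weight.data.shape
    xpad = np.pad(x.data, ((0, 0), (0, 0), pad))
    L_out = (xpad.shape[-1] - k) // stride + 1
    taps = [xpad[:, :, i:i + stride * L_out:stride] for i in range(k)]
    out_data = np.zeros((B, D, L_out), dtype=xpad.dtype)
    for i in range(k):
        out_data += np.einsum("bcl,dc->bdl", taps[i], weight.data[:, :, i],
                              optimize=True)
    out_data += bias.data[:, None]

    def backward(g):
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for i in range(k):
                gw[:, :, i] = np.einsum("bdl,bcl->dc", g, taps[i], optimize=True)
            weight._accumulate(gw)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xpad)
            for i in range(k):
                gxp[:, :, i:i + stride * L_out:stride] += np.einsum(
                    "bdl,dc->bcl", g, weight.data[:, :, i], optimize=True)
            lo, hi = pad[0], pad[0] + L
            x._accumulate(gxp[:, :, lo:hi])

    return Tensor._make(out_data, (x, weight, bias), backward)


class Conv1d(Module):
    """Temporal convolution over [B, C, L] with same-style padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_channels))
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] < self.kernel:
            raise ValueError("input shorter than kernel")
        half = self.kernel // 2
        return _conv1d_primitive(x, self.weight, self.bias, self.stride, (half, half))


def _conv2d_primitive(x: Tensor, weight: Tensor, bias: Tensor | None,
                      pad: int, depthwise: bool) -> Tensor:
    """x: [B, C, H, W]; weight: [D, C, k, k] or depthwise [C, k, k]."""
    B, C, H, W = x.data.shape
    k = weight.data.shape[-1]
    xpad = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho, Wo = xpad.shape[2] - k + 1, xpad.shape[3] - k + 1
    D = C if depthwise else weight.data.shape[0]
    # shift-and-add over the k*k taps; avoids materializing im2col windows
    out_data = np.zeros((B, D, Ho, Wo), dtype=xpad.dtype)
    for i in range(k):
        for j in range(k):
            sl = xpad[:, :, i:i + Ho, j:j + Wo]
            if depthwise:
                out_data += sl * weight.data[:, i, j][:, None, None]
            else:
                out_data += np.einsum("bchw,dc->bdhw", sl,
                                      weight.data[:, :, i, j], optimize=True)
    if bias is not None:
        out_data += bias.data[:, None, None]

    def backward(g):
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for i in range(k):
                for j in range(k):
                    sl = xpad[:, :, i:i + Ho, j:j + Wo]
                    if depthwise:
                        gw[:, i, j] = (g * sl).sum(axis=(0, 2, 3))
                    else:
                        gw[:, :, i, j] = np.einsum("bdhw,bchw->dc", g, sl,
                                                   optimize=True)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xpad)
            for i in range(k):
                for j in range(k):
                    if depthwise:
                        gxp[:, :, i:i + Ho, j:j + Wo] += g * weight.data[:, i, j][:, None, None]
                    else:
                        gxp[:, :, i:i + Ho, j:j + Wo] += np.einsum(
                            "bdhw,dc->bchw", g, weight.data[:, :, i, j], optimize=True)
            x._accumulate(gxp[:, :, pad:pad + H, pad:pad + W])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(
            _kaiming(rng, (out_channels, in_channels, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_channels))
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return _conv2d_primitive(x, self.weight, self.bias, self.kernel // 2, False)


class DepthwiseConv2d(Module):
    """Per-channel spatial convolution (the ConvNeXt-style depthwise conv)."""

    def __init__(self, channels: int, kernel: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (channels, kernel, kernel), kernel * kernel))
        self.bias = Parameter(np.zeros(channels))
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return _conv2d_primitive(x, self.weight, self.bias, self.kernel // 2, True)


class LayerNorm(Module):
    """Normalize over the trailing ``shape`` dims; learnable affine."""

    def __init__(self, shape: int | tuple[int, ...], eps: float = 1e-5):
        super().__init__()
        if isinstance(shape, int):
            shape = (shape,)
        self.gamma = Parameter(np.ones(shape))
        self.beta = Parameter(np.zeros(shape))
        self.eps = eps
        self._axes = tuple(range(-len(shape), 0))

    def normalized(self, x: Tensor) -> Tensor:
        """The pre-affine standardized values (each row mean 0, var 1)."""
        mu = x.mean(axis=self._axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=self._axes, keepdims=True)
        return xc * ((var + self.eps) ** -0.5)

    def forward(self, x: Tensor) -> Tensor:
        return self.normalized(x) * self.gamma + self.beta


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
        else:
            mu = Tensor(self.running_mean[None, :, None, None])
            xc = x - mu
            var = Tensor(self.running_var[None, :, None, None])
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class MaxPool2d(Module):
    """Non-overlapping max pooling; ``kernel`` is an int or (kh, kw) pair."""

    def __init__(self, kernel: int | tuple[int, int] = 2):
        super().__init__()
        self.kernel = (kernel, kernel) if isinstance(kernel, int) else tuple(kernel)

    def forward(self, x: Tensor) -> Tensor:
        kh, kw = self.kernel
        B, C, H, W = x.shape
        Ho, Wo = H // kh, W // kw
        if Ho < 1 or Wo < 1:
            raise ValueError("input smaller than pooling window")
        cropped = x[:, :, :Ho * kh, :Wo * kw]
        tiles = cropped.reshape(B, C, Ho, kh, Wo, kw).transpose(0, 1, 2, 4, 3, 5)
        flat = tiles.reshape(B, C, Ho, Wo, kh * kw)
        return flat.max(axis=-1)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        setattr(self, str(len(self._list)), module)
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def gradient_reversal(x: Tensor, lam: float) -> Tensor:
    """Identity forward; backward multiplies incoming gradients by ``-lam``."""
    if lam < 0:
        raise ValueError("gradient-reversal strength must be >= 0")

    def backward(g):
        if x.requires_grad:
            x._accumulate(-lam * g)

    return Tensor._make(x.data.copy(), (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def clip_gradients_(params: list[Tensor], clip_abs: float) -> None:
    """Elementwise clip of every gradient to [-clip_abs, +clip_abs]."""
    for p in params:
        if p.grad is not None:
            np.clip(p.grad, -clip_abs, clip_abs, out=p.grad)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
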