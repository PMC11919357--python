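"""Neural-network layers built on the autodiff core.

Layout convention is NCHW. Every layer draws its initial weights from an
``numpy.random.Generator`` passed in at construction, so a model seed fully
determines the parameter values.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Parameter, Tensor

__all__ = [
    "Module", "Conv2d", "ConvTranspose2d", "DepthwiseConv2d", "Dense",
    "ChannelLayerNorm", "InstanceNorm", "LayerNorm", "SEBlock", "Adam",
]


class Module:
    """Minimal container with recursive parameter discovery."""

    def named_parameters(self, prefix: str = ""):
        def walk(key, val):
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    yield from walk(f"{key}.{i}", item)

        for name, val in vars(self).items():
            yield from walk(f"{prefix}{name}", val)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.weight = Parameter(_he(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, pad=self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, c: int, k: int, rng: np.random.Generator,
                 stride: int = 1):
        self.stride = stride
        self.pad = k // 2
        self.groups = c
        self.weight = Parameter(_he(rng, (c, 1, k, k), k * k))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         pad=self.pad, groups=self.groups)


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution (output side doubles)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 2):
        if k % 2 == 0:
            raise ValueError("odd kernels only")
        self.stride = stride
        self.k = k
        self.weight = Parameter(_he(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        p = self.k // 2
        # dilate + pad + unit-stride correlation == transposed conv with
        # padding k//2 and output_padding stride-1 (output = stride * input)
        y = ad.dilate2d(x, self.stride, extra=self.stride - 1)
        y = ad.pad2d(y, self.k - 1 - p)
        return ad.conv2d(y, self.weight, self.bias, stride=1, pad=0)


class Dense(Module):
    """Linear projection applied to the trailing axis (Glorot init)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin + cout))
        self.weight = Parameter(
            rng.normal(0.0, std, size=(cin, cout)).astype(np.float32))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta)


class ChannelLayerNorm(Module):
    """Layer normalisation over the channel axis of NCHW features."""

    def __init__(self, c: int):
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.transpose(x, (0, 2, 3, 1))
        y = ad.layer_norm(y, self.gamma, self.beta)
        return ad.transpose(y, (0, 3, 1, 2))


class SEBlock(Module):
    """Squeeze-and-excitation channel gate (global pool -> bottleneck ->
    sigmoid -> channel-wise rescale)."""

    def __init__(self, c: int, rng: np.random.Generator, reduction: int = 8):
        if c < reduction:
            raise ValueError(f"channels ({c}) must be >= reduction "
                             f"({reduction})")
        self.fc1 = Dense(c, c // reduction, rng)
        self.fc2 = Dense(c // reduction, c, rng)
        self.c = c

    def gate(self, x: Tensor) -> Tensor:
        z = ad.mean(x, axis=(2, 3))                    # (N, C)
        z = self.fc2(ad.gelu(self.fc1(z)))
        return ad.sigmoid(z)

    def __call__(self, x: Tensor) -> Tensor:
        g = ad.reshape(self.gate(x), (-1, self.c, 1, 1))
        return ad.mul(x, g)


class Adam:
    """Adam optimiser (TensorFlow-default epsilon)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class InstanceNorm(Module):
    """Per-channel spatial normalisation of NCHW features (affine).

    Unlike channel-wise layer normalisation this preserves each pixel's
    relative intensity within its channel, which matters at the narrow
    stem widths where per-pixel channel statistics are nearly degenerate.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((c, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((c, 1), dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        y = ad.reshape(x, (n, c, h * w))
        y = ad.layer_norm(y, self.gamma, self.beta, eps=self.eps)
        return ad.reshape(y, (n, c, h, w))
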