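"""Layer and optimizer building blocks on top of the autograd engine.

Every convolution (plain and transposed) carries spectral normalization:
the weight used in the forward pass is the raw parameter divided by its
leading singular value, estimated by one persistent power-iteration step
per call.  The singular-vector pair is treated as constant in the
gradient, so the normalization itself stays differentiable through the
division.
"""

from __future__ import annotations

from typing import Iterator, List

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "Adam", "init_normal"]

INIT_STD = 0.02  # Gaussian(0, 0.02) weight initialization


def init_normal(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.normal(0.0, INIT_STD, size=shape)


class Module:
    """Tiny nn.Module analogue: named parameters, recursive traversal."""

    def parameters(self) -> List[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def _named_sn_states(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, _SpectralWeight):
                yield full, value
            elif isinstance(value, Module):
                yield from value._named_sn_states(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_sn_states(f"{full}.{i}.")

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"{name}.u": sn.u.copy() for name, sn in self._named_sn_states()})
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state: {sorted(missing)}")
        for name, p in own.items():
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=float).copy()
        for name, sn in self._named_sn_states():
            key = f"{name}.u"
            if key in state:
                sn.u = np.asarray(state[key], dtype=float).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class _SpectralWeight:
    """Power-iteration spectral norm state for one weight matrix view."""

    def __init__(self, weight: Tensor, rng: np.random.Generator):
        self.weight = weight
        rows = weight.shape[0]
        u = rng.standard_normal(rows)
        self.u = u / np.linalg.norm(u)

    def normalized(self) -> Tensor:
        w = self.weight
        wmat = w.data.reshape(w.shape[0], -1)
        v = wmat.T @ self.u
        v /= np.linalg.norm(v) + 1e-12
        u = wmat @ v
        u /= np.linalg.norm(u) + 1e-12
        if ag._GRAD_ENABLED:
            # power iteration advances only during training passes so
            # that inference is a pure function of the stored state
            self.u = u
        sigma_value = float(u @ wmat @ v)
        if abs(sigma_value) < 1e-12:  # degenerate (e.g. zeroed) weight
            return w
        # sigma = u^T W v, expressed through the graph with (u, v) constant
        uv = Tensor(np.outer(u, v).reshape(w.shape))
        sigma = ag.tsum(ag.mul(w, uv))
        return ag.mul(w, ag.reciprocal(sigma))


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        spectral_norm: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        self.stride = stride
        self.padding = padding
        self.kernel = kernel
        self.spectral_norm = spectral_norm
        self.weight = Tensor(
            init_normal(rng, (out_channels, in_channels, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self._sn = _SpectralWeight(self.weight, rng) if spectral_norm else None

    def effective_weight(self) -> Tensor:
        if self._sn is not None:
            return self._sn.normalized()
        return self.weight

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(
            x, self.effective_weight(), self.bias, stride=self.stride, padding=self.padding
        )


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution with a 3x3 kernel, realized as
    zero-insertion dilation (with one row/column of output padding)
    followed by a unit-stride convolution; doubles the spatial size
    exactly."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 2,
        spectral_norm: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        if kernel % 2 == 0:
            raise ValueError("odd kernels only")
        self.stride = stride
        self.kernel = kernel
        self.spectral_norm = spectral_norm
        self.weight = Tensor(
            init_normal(rng, (out_channels, in_channels, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self._sn = _SpectralWeight(self.weight, rng) if spectral_norm else None

    def forward(self, x: Tensor) -> Tensor:
        w = self._sn.normalized() if self._sn is not None else self.weight
        pad = self.kernel // 2
        dilated = ag.dilate2d(x, self.stride, extra=self.stride - 1)
        return ag.conv2d(dilated, w, self.bias, stride=1, padding=pad)


class Adam:
    """Adam with the GAN-customary first moment 0.5."""

    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
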