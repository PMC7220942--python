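"""Trainable layers and the Adam optimizer for the 1-D conv network."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Layer", "Conv1d", "BatchNorm1d", "Dense", "Adam"]


class Layer:
    """Base: tracks parameters and a training/eval flag."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Layer):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters plus non-trainable state."""
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            if isinstance(v, Tensor):
                out[name] = v.data
            elif isinstance(v, np.ndarray):
                out[name] = v
            elif isinstance(v, Layer):
                for sub, arr in v.state_arrays().items():
                    out[f"{name}.{sub}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Layer):
                        for sub, arr in item.state_arrays().items():
                            out[f"{name}.{i}.{sub}"] = arr
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = np.asarray(state[key], dtype=np.float64)
            elif isinstance(v, np.ndarray):
                setattr(self, name, np.asarray(state[key], dtype=np.float64))
            elif isinstance(v, Layer):
                v.load_state_arrays(state, prefix=f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Layer):
                        item.load_state_arrays(state, prefix=f"{key}.{i}.")


class Conv1d(Layer):
    """Same-padded 1-D convolution; He-initialized weights."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size)),
            requires_grad=True,
        )
        # non-zero bias init keeps binary inputs off the exact relu kink
        bound = 1.0 / np.sqrt(fan_in)
        self.bias = Tensor(
            rng.uniform(-bound, bound, size=out_channels), requires_grad=True
        )
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (N, L) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.data.mean(axis=(0, 2))
            var = x.data.var(axis=(0, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None]) * inv_std[None, :, None]
        y = self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]
        out = Tensor(y, parents=(x, self.gamma, self.beta))
        m = x.data.shape[0] * x.data.shape[2]  # samples per channel

        def _bw(g: np.ndarray) -> None:
            self.gamma.accumulate((g * xhat).sum(axis=(0, 2)))
            self.beta.accumulate(g.sum(axis=(0, 2)))
            if not x.requires_grad:
                return
            gxhat = g * self.gamma.data[None, :, None]
            if training:
                # batch statistics depend on x: full batchnorm backward
                sum_g = gxhat.sum(axis=(0, 2), keepdims=True)
                sum_gx = (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
                dx = (
                    inv_std[None, :, None]
                    * (gxhat - sum_g / m - xhat * sum_gx / m)
                )
            else:
                dx = gxhat * inv_std[None, :, None]
            x.accumulate(dx)

        out._backward = _bw
        return out


class Dense(Layer):
    """Fully connected layer on (N, F) inputs."""

    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator | None = None
    ):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_features, out_features)),
            requires_grad=True,
        )
        bound = 1.0 / np.sqrt(in_features)
        self.bias = Tensor(
            rng.uniform(-bound, bound, size=out_features), requires_grad=True
        )

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Adam:
    """Adam optimizer with bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

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
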