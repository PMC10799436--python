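"""Neural-network modules and the Adam optimizer on the autodiff backend.

Layers follow the usual conventions: ``Module`` tracks parameters and
submodules through attribute assignment, ``train()``/``eval()`` toggle
batch-statistics and dropout behaviour, and ``state_dict`` round-trips all
parameters and buffers by dotted name.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._tensor import Tensor, conv3d, max_pool3d

__all__ = [
    "Parameter", "Module", "Conv3d", "Linear", "BatchNorm3d", "LayerNorm",
    "MaxPool3d", "Dropout", "Adam", "he_init",
]


class Parameter(Tensor):
    """A trainable tensor, optionally clamped to an interval after updates."""

    __slots__ = ("clamp", "lr_scale")

    def __init__(self, data, clamp: tuple[float, float] | None = None,
                 lr_scale: float = 1.0):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.clamp = clamp
        self.lr_scale = lr_scale


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state["buffer:" + name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            if key.startswith("buffer:"):
                path = key[len("buffer:"):]
                *mods, leaf = path.split(".")
                target: Module = self
                for m in mods:
                    target = target._modules[m]
                value = np.asarray(value)
                target._buffers[leaf] = value
                object.__setattr__(target, leaf, value)
            else:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {key!r}")
                params[key].data = np.asarray(value, dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3d(Module):
    """3D convolution, zero 'same' padding by default, optional bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: str | int = "same", bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(he_init(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm3d(Module):
    """Per-channel batch normalization over (B, D, H, W) of a (B,C,D,H,W) map.

    Training mode normalizes with batch statistics and updates running
    moments; eval mode uses the running moments, making inference per-sample
    pure.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(n_ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(n_ch, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(n_ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(n_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu).pow(2.0)).mean(axis=axes, keepdims=True)
            m = self.momentum
            new_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            new_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            self._buffers["running_mean"] = new_mean.astype(np.float32)
            self._buffers["running_var"] = new_var.astype(np.float32)
            object.__setattr__(self, "running_mean", self._buffers["running_mean"])
            object.__setattr__(self, "running_var", self._buffers["running_var"])
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1, 1))
        xhat = (x - mu) * (var + self.eps).pow(-0.5)
        g = self.gamma.reshape(1, -1, 1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Layer normalization over the trailing dimension."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu).pow(2.0)).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * (var + self.eps).pow(-0.5)
        return xhat * self.gamma + self.beta


class MaxPool3d(Module):
    def __init__(self, window: int = 2):
        super().__init__()
        self.window = window

    def forward(self, x: Tensor) -> Tensor:
        return max_pool3d(x, self.window)


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class Adam:
    """Adam with per-parameter learning-rate scaling and post-step clamping.

    ``lr`` may be reassigned between steps to implement schedules.  After each
    update, parameters carrying a ``clamp`` interval are projected back into
    it (used by the attention gate, which must stay in [0, 1]).
    """

    def __init__(self, params, lr: float = 1e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / b1t
            vhat = v / b2t
            scale = getattr(p, "lr_scale", 1.0)
            p.data -= (self.lr * scale) * mhat / (np.sqrt(vhat) + self.eps)
            clamp = getattr(p, "clamp", None)
            if clamp is not None:
                np.clip(p.data, clamp[0], clamp[1], out=p.data)
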