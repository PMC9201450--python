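"""Network building blocks and optimizers on top of the autograd engine.

Layers follow the usual conventions: convolutions are cross-correlations on
NCHW tensors, batch normalization keeps running statistics for evaluation
mode, layer normalization acts over the trailing feature axis.  Parameters
are float64 ``Tensor`` objects; initialization is fan-in-scaled ("He")
normal for convolutions and linear maps unless noted.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._tensor import Tensor, conv2d

__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "LayerNorm", "Linear", "Sequential",
    "ReLU", "GELU", "SGD", "ReduceLROnPlateau",
]


class Module:
    """Base class: parameter/submodule registration and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({"buffer:" + n: b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("buffer:"):
                self._assign_buffer(name[len("buffer:"):], value)
            else:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name}")
                params[name].data = value.copy()

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            mod = mod._modules[part]
        mod._buffers[parts[-1]] = value.copy()
        object.__setattr__(mod, parts[-1], mod._buffers[parts[-1]])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int | None = None, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c_in % groups or c_out % groups:
            raise ValueError("groups must divide both channel counts")
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.groups = groups
        fan_in = (c_in // groups) * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in // groups, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self._buffers["running_mean"] *= (1 - self.momentum)
            self._buffers["running_mean"] += self.momentum * mean.data.reshape(c)
            self._buffers["running_var"] *= (1 - self.momentum)
            self._buffers["running_var"] += self.momentum * var.data.reshape(c)
            object.__setattr__(self, "running_mean", self._buffers["running_mean"])
            object.__setattr__(self, "running_var", self._buffers["running_var"])
        else:
            mean = Tensor(self._buffers["running_mean"].reshape(1, c, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, c, 1, 1))
        xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    """Normalize over the last axis; affine rescale is learned."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer
            object.__setattr__(self, str(i), layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` when the tracked loss stalls."""

    def __init__(self, optimizer: SGD, factor: float = 0.3, patience: int = 10,
                 min_lr: float = 1e-6, rel_eps: float = 1e-4):
        if not 0 < factor < 1:
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.rel_eps = rel_eps
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best * (1 - self.rel_eps):
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
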