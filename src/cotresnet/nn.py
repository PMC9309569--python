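"""Neural-network layers composed from the autodiff primitives.

Conventions follow the standard residual-network recipe: convolutions carry
no bias when a batch-norm follows, weights use He-normal initialisation, and
batch-norm keeps running statistics for inference mode.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, unfold_nbhd

__all__ = [
    "Module",
    "Sequential",
    "Identity",
    "ReLU",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "MaxPool2d",
    "AvgPool2d",
    "global_avg_pool",
]


class Module:
    """Base class: parameter traversal, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    # -- traversal -----------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self):
        self.training = True
        for _, child in self.children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self.children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- serialization -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": p.data for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b for k, b in self.named_buffers()})
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        expected = {f"param:{k}" for k in params} | {
            f"buffer:{k}" for k, _ in self.named_buffers()
        }
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise ValueError(f"state mismatch: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}")
        for key, arr in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                p = params[name]
                if p.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {arr.shape}")
                p.data = arr.astype(p.data.dtype).copy()
            else:
                # buffers are resolved by attribute path
                obj = self
                *path, leaf = name.split(".")
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                setattr(obj, leaf, arr.copy())


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __getitem__(self, i: int) -> Module:
        return self.layers[i]


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Conv2d(Module):
    """2-D convolution (optionally grouped) via im2col + matmul."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        *,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channel counts (in={in_channels}, out={out_channels}) "
                f"must be divisible by groups g={groups}"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels // groups, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, g = self.kernel_size, self.groups
        cols = unfold_nbhd(x, k, stride=self.stride, padding=self.padding)
        _, _, _, ho, wo = cols.shape
        if g == 1:
            flat = cols.reshape((n, c * k * k, ho * wo))
            w2 = self.weight.reshape((self.out_channels, c * k * k))
            out = (w2 @ flat).reshape((n, self.out_channels, ho, wo))
        else:
            cg, og = c // g, self.out_channels // g
            # (N, g, cg*k*k, L) and per-group weight matmul in one batched call
            grouped = cols.reshape((n, g, cg * k * k, ho * wo))
            w2 = self.weight.reshape((g, og, cg * k * k))
            out = (w2 @ grouped).reshape((n, self.out_channels, ho, wo))
        if self.bias is not None:
            out = out + self.bias.reshape((1, self.out_channels, 1, 1))
        return out

    def weight_count(self) -> int:
        n = self.weight.data.size
        if self.bias is not None:
            n += self.bias.data.size
        return n


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        c = self.channels
        if x.shape[1] != c:
            raise ValueError(f"expected {c} channels, got {x.shape[1]}")
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            nhw = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(c) * (nhw / max(nhw - 1, 1))
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return self.gamma.reshape((1, c, 1, 1)) * xhat + self.beta.reshape((1, c, 1, 1))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose((1, 0))
        if self.bias is not None:
            out = out + self.bias
        return out


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        cols = unfold_nbhd(
            x, self.kernel_size, stride=self.stride, padding=self.padding, pad_value=-np.inf
        )
        return cols.max(axis=2)


class AvgPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        cols = unfold_nbhd(x, self.kernel_size, stride=self.stride, padding=self.padding)
        return cols.mean(axis=2)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial average."""
    return x.mean(axis=(2, 3))
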