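"""Layer/module abstractions over the autograd core.

Modules own parameter tensors and compose; initialization is explicit
about its RNG so two builds with the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, avg_pool2d, concat, conv2d, max_pool2d


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def astype(self, dtype) -> "Module":
        """Cast all parameters in place (float32 speeds up training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    @property
    def dtype(self):
        params = self.parameters()
        return params[0].data.dtype if params else np.float64

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, arr in zip(params, state):
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """3x3/1x1/etc. convolution with He-normal initialization."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | str = "same", bias: bool = True):
        if padding == "same":
            padding = k // 2
        self.stride = stride
        self.padding = int(padding)
        std = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Tensor(rng.normal(0, std, (c_out, c_in, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / f_in)
        self.weight = Tensor(rng.normal(0, std, (f_in, f_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(f_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class SEBlock(Module):
    """Squeeze-and-excitation channel recalibration.

    Global average pool per channel -> FC down to C // reduction with
    ReLU -> FC back to C with sigmoid -> channelwise rescale.  The
    bottleneck width is clamped to >= 1 (with a warning) when the
    reduction exceeds the channel count.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        import warnings

        hidden = channels // reduction
        if hidden < 1:
            warnings.warn(
                f"SEBlock: channels={channels} < reduction={reduction}; "
                "clamping bottleneck width to 1",
                stacklevel=2,
            )
            hidden = 1
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        squeezed = x.mean(axis=(2, 3))  # (N, C)
        scale = self.fc2(self.fc1(squeezed).relu()).sigmoid()
        return x * scale.reshape(n, c, 1, 1)


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.k)


class AvgPool2d(Module):
    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2d(x, self.k)


__all__ = [
    "Module", "Conv2d", "Linear", "ReLU", "Sigmoid", "Sequential",
    "SEBlock", "MaxPool2d", "AvgPool2d", "concat",
]
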