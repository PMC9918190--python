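"""Neural-network building blocks on top of the autograd tensor.

Modules hold named parameters (He-initialised from a caller-supplied RNG so
every training run is reproducible), expose ``state_dict``/``load_state_dict``
for checkpointing via ``np.savez``, and compose through ``Sequential``.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, avg_pool2d, concat, conv2d, upsample2x

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Sequential",
    "ResidualBlock",
    "UpsampleConv",
    "GlobalAvgPool",
    "Flatten",
]


class Module:
    """Base class: child modules and parameters discovered by attribute scan."""

    def parameters(self) -> list[Tensor]:
        """All parameter tensors, trainable or frozen."""
        params: list[Tensor] = []
        for _, value in sorted(vars(self).items()):
            if isinstance(value, Tensor):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in sorted(vars(self).items()):
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict keys do not match parameters: {sorted(missing)}")
        for k, v in params.items():
            v.data[...] = state[k]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0.0, scale, (cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / nin)
        self.weight = Tensor(rng.normal(0.0, scale, (nin, nout)), requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class GlobalAvgPool(Module):
    """Mean over the spatial axes of an NCHW tensor."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ResidualBlock(Module):
    """Two 3x3 convolutions with an identity (or 1x1-projected) shortcut.

    The residual topology of the classifier and segmenter encoders; stride 2
    in the first convolution halves the resolution, mirroring the downsampling
    stages of the standard residual image backbones.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu())
        shortcut = x if self.proj is None else self.proj(x)
        return (h + shortcut).relu()


class UpsampleConv(Module):
    """Nearest-neighbour 2x upsampling followed by a 3x3 convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        self.conv = Conv2d(cin, cout, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(upsample2x(x))
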