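"""Trainable layers and the tiny-tier denoising networks.

The tiny tier is the CPU-trainable counterpart of the full-scale
architectures described in :mod:`petbench.models.archspec`: small
stride-1 convolutional stacks (2D, 2.5D multi-channel, or 3D) that predict
the noise residual and are wrapped as ``x + net(x)``.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv_nd


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError


class Conv(Module):
    """N-d convolution; weights drawn N(0, 0.02) as in image-translation
    GAN practice, biases zero."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, nd: int = 2,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        k = (kernel,) * nd
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(out_ch, in_ch, *k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias \
            else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias, stride=self.stride,
                       padding=self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ResidualBlock(Module):
    def __init__(self, ch: int, kernel: int = 3, nd: int = 2,
                 rng: np.random.Generator | None = None):
        self.body = Sequential(
            Conv(ch, ch, kernel, nd=nd, rng=rng), ReLU(),
            Conv(ch, ch, kernel, nd=nd, rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return x + self.body(x)


class TinyResNet(Module):
    """Stride-1 residual CNN predicting the noise residual.

    ``in_ch`` is 1 for plain 2D, 2k+1 for the 2.5D stacking, and the output
    is always the (single-channel) central-slice residual.  With ``nd=3``
    the same stack acts on 32-slice chunks as the 3D stand-in network.
    """

    def __init__(self, in_ch: int = 1, width: int = 8, depth: int = 2,
                 kernel: int = 3, nd: int = 2, seed: int = 0):
        if width < 4:
            raise ValueError("width must be at least 4")
        rng = np.random.default_rng(seed)
        mods: list[Module] = [Conv(in_ch, width, kernel, nd=nd, rng=rng),
                              ReLU()]
        for _ in range(depth):
            mods += [ResidualBlock(width, kernel, nd=nd, rng=rng)]
        mods += [Conv(width, 1, kernel, nd=nd, rng=rng)]
        self.net = Sequential(*mods)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class TinyPatchDiscriminator(Module):
    """Downsampling convolutional stack emitting a patch realness map."""

    def __init__(self, in_ch: int = 1, width: int = 8, n_layers: int = 2,
                 nd: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        mods: list[Module] = [
            Conv(in_ch, width, 4, nd=nd, stride=2, padding=1, rng=rng),
            LeakyReLU(),
        ]
        ch = width
        for _ in range(n_layers - 1):
            mods += [Conv(ch, 2 * ch, 4, nd=nd, stride=2, padding=1, rng=rng),
                     LeakyReLU()]
            ch *= 2
        mods += [Conv(ch, 1, 3, nd=nd, rng=rng)]
        self.net = Sequential(*mods)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)
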