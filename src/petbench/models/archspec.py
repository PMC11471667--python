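"""Full-scale network architecture specifications and parameter accounting.

The full-scale generators and discriminators follow the reference
CycleGAN/pix2pix layer structure: a 256-resolution U-Net generator with 8
stride-2 4x4 encoder convolutions (widths 64, 128, 256, 512, 512, 512, 512,
512), a mirrored transposed-convolution decoder with skip concatenation and
batch normalization; a ResNet-style down/up generator with residual blocks
at base width 64; and a 3-layer PatchGAN discriminator (widths 64/128/256
stride-2, width-512 stride-1, final 1-channel map; no normalization on the
first layer).  These are represented as layer descriptions so the exact
trainable-parameter count is available without a deep-learning runtime;
CPU-trainable "tiny" instances live in :mod:`petbench.models.layers`.

With batch normalization, convolutions followed by a norm layer carry no
bias (the norm's shift absorbs it); the outermost decoder convolution and
the first/last discriminator convolutions keep their biases.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod

UNET_WIDTHS = (64, 128, 256, 512, 512, 512, 512, 512)


@dataclass(frozen=True)
class LayerSpec:
    """One parameterized layer: a convolution or a normalization."""

    kind: str  # conv | conv_transpose | norm
    in_ch: int
    out_ch: int
    kernel: tuple[int, ...] = ()
    bias: bool = False

    @property
    def n_params(self) -> int:
        if self.kind == "norm":
            return 2 * self.out_ch  # affine scale + shift
        n = self.out_ch * self.in_ch * prod(self.kernel)
        return n + (self.out_ch if self.bias else 0)


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    layers: tuple[LayerSpec, ...]
    input_size: int = 256


@dataclass(frozen=True)
class ModelConfig:
    """Selects a denoiser family and its capacity tier.

    ``channels`` is 1 for plain 2D or 2k+1 for the 2.5D slice stacking and
    must be odd; the ``tiny`` tier is CPU-trainable, the ``full`` tier is
    the full-scale architecture (specification only, unless an external
    runtime is plugged in).
    """

    family: str = "resnet_gen"  # gaussian | resnet_gen | unet_gen | simple3d
    channels: int = 1
    width: int = 64
    depth: int = 2
    residual: bool = True
    tier: str = "full"  # full | tiny

    def __post_init__(self) -> None:
        if self.channels % 2 == 0:
            raise ValueError("input channel count must be odd (2k+1)")
        if self.width < 4:
            raise ValueError("width must be at least 4")
        if self.family not in ("gaussian", "resnet_gen", "unet_gen",
                               "simple3d"):
            raise ValueError(f"unknown family {self.family!r}")


def _conv(cin, cout, k=4, bias=False):
    return LayerSpec("conv", cin, cout, (k, k), bias)


def _deconv(cin, cout, k=4, bias=False):
    return LayerSpec("conv_transpose", cin, cout, (k, k), bias)


def _norm(c):
    return LayerSpec("norm", c, c)


def build_unet_generator(in_ch: int = 1, out_ch: int = 1,
                         widths=UNET_WIDTHS,
                         input_size: int = 256) -> NetworkSpec:
    """U-Net generator spec with skip concatenation (unet_256 layout)."""
    n_downs = len(widths)
    if input_size % (2 ** n_downs) != 0 or input_size < 2 ** n_downs:
        raise ValueError(
            f"{n_downs} stride-2 stages are inconsistent with a "
            f"{input_size} input grid")
    layers: list[LayerSpec] = []
    # encoder: outermost and innermost down-convs have no norm after them
    layers.append(_conv(in_ch, widths[0]))
    for i in range(1, n_downs):
        layers.append(_conv(widths[i - 1], widths[i]))
        if i != n_downs - 1:
            layers.append(_norm(widths[i]))
    # decoder, innermost out: first up-conv sees no skip concat
    layers.append(_deconv(widths[-1], widths[-2]))
    layers.append(_norm(widths[-2]))
    for i in range(n_downs - 2, 0, -1):
        layers.append(_deconv(2 * widths[i], widths[i - 1]))
        layers.append(_norm(widths[i - 1]))
    layers.append(_deconv(2 * widths[0], out_ch, bias=True))
    return NetworkSpec("unet_gen", tuple(layers), input_size)


def build_resnet_generator(in_ch: int = 1, out_ch: int = 1, base: int = 64,
                           n_blocks: int = 9,
                           input_size: int = 256) -> NetworkSpec:
    """ResNet-style down/up generator at base width 64.

    The decoder uses transposed convolutions without skip connections.
    """
    if input_size % 4 != 0:
        raise ValueError("two stride-2 stages need a grid divisible by 4")
    layers: list[LayerSpec] = [
        LayerSpec("conv", in_ch, base, (7, 7)), _norm(base),
        _conv(base, 2 * base, 3), _norm(2 * base),
        _conv(2 * base, 4 * base, 3), _norm(4 * base),
    ]
    for _ in range(n_blocks):
        layers += [LayerSpec("conv", 4 * base, 4 * base, (3, 3)),
                   _norm(4 * base),
                   LayerSpec("conv", 4 * base, 4 * base, (3, 3)),
                   _norm(4 * base)]
    layers += [
        _deconv(4 * base, 2 * base, 3), _norm(2 * base),
        _deconv(2 * base, base, 3), _norm(base),
        LayerSpec("conv", base, out_ch, (7, 7), bias=True),
    ]
    return NetworkSpec("resnet_gen", tuple(layers), input_size)


def build_patch_discriminator(in_ch: int = 2, ndf: int = 64,
                              n_layers: int = 3,
                              input_size: int = 256) -> NetworkSpec:
    """PatchGAN spec: stride-2 4x4 stack, no norm on the first layer.

    ``in_ch=2`` is the paired-input (or image-difference) configuration a
    pix2pix-style difference discriminator consumes.
    """
    layers: list[LayerSpec] = [_conv(in_ch, ndf, bias=True)]
    ch = ndf
    for _ in range(1, n_layers):
        layers += [_conv(ch, 2 * ch), _norm(2 * ch)]
        ch *= 2
    layers += [_conv(ch, 2 * ch), _norm(2 * ch)]  # stride-1 width-512 stage
    layers += [_conv(2 * ch, 1, bias=True)]  # 1-channel realness map
    return NetworkSpec("patchgan", tuple(layers), input_size)


def build_generator(config: ModelConfig, in_ch: int | None = None,
                    input_size: int = 256):
    """Network spec (full tier) or trainable network (tiny tier)."""
    in_ch = config.channels if in_ch is None else in_ch
    if config.tier == "tiny":
        from .layers import TinyResNet
        nd = 3 if config.family == "simple3d" else 2
        return TinyResNet(in_ch=in_ch, width=config.width,
                          depth=config.depth, nd=nd)
    if config.family == "unet_gen":
        return build_unet_generator(in_ch, 1, input_size=input_size)
    if config.family == "resnet_gen":
        return build_resnet_generator(in_ch, 1, base=config.width,
                                      input_size=input_size)
    raise ValueError(f"no full-tier spec for family {config.family!r}")


def build_discriminator(config: ModelConfig, in_ch: int = 2,
                        input_size: int = 256):
    if config.tier == "tiny":
        from .layers import TinyPatchDiscriminator
        return TinyPatchDiscriminator(in_ch=in_ch, width=config.width)
    return build_patch_discriminator(in_ch, input_size=input_size)


def count_parameters(net) -> int:
    """Exact trainable-parameter count of a spec or runtime network."""
    if isinstance(net, NetworkSpec):
        return sum(layer.n_params for layer in net.layers)
    return net.n_parameters()
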