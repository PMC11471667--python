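"""Loss framework for the denoiser zoo.

Conventions (``G`` denoises LT -> FT, ``F`` re-noises FT -> LT):

* identity loss       sum_i ||G(FT_i) - FT_i||_1 + ||F(LT_i) - LT_i||_1
  (keeps the generators from altering already-clean images);
* reconstruction loss (1/n) sum_i ||G(LT_i) - FT_i||_1
  (the supervised pairing term added to CycleGAN);
* image-prior loss    sum_i ||G(LT_i) - LT_i||_1
  (regularizes the denoised output toward its own input, exploiting that LT
  and FT slices of the same session are already similar);
* cycle loss          ||F(G(LT)) - LT||_1 + ||G(F(FT)) - FT||_1;
* adversarial loss    least-squares GAN objective; the pix2pix
  discriminator consumes the image *difference* (denoised - input) rather
  than the image itself.

``||.||_1`` sums absolute values over all voxels of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, _as_tensor


@dataclass(frozen=True)
class LossConfig:
    """Weights of the composite objective.

    Defaults follow the tuned study configuration: identity 2.2, image
    prior 9.2, supervised reconstruction 9.2, pix2pix distance 10.0; the
    cycle-consistency weight is the conventional 10.0.
    """

    l1: float = 1.0
    charbonnier: float = 0.0
    adversarial: float = 1.0
    cycle: float = 10.0
    identity: float = 2.2
    image_prior: float = 9.2
    reconstruction: float = 9.2
    pix2pix_distance: float = 10.0
    charbonnier_eps: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("l1", "charbonnier", "adversarial", "cycle", "identity",
                     "image_prior", "reconstruction", "pix2pix_distance"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss coefficient {name} must be >= 0")


def _check_shapes(a, b) -> None:
    sa = a.data.shape if isinstance(a, Tensor) else np.shape(a)
    sb = b.data.shape if isinstance(b, Tensor) else np.shape(b)
    if sa != sb:
        raise ValueError(f"shape mismatch {sa} vs {sb}")


def loss_l1(a, b) -> Tensor:
    """Mean absolute difference."""
    _check_shapes(a, b)
    return (_as_tensor(a) - _as_tensor(b)).mean_abs()


def loss_charbonnier(a, b, eps: float = 1e-3) -> Tensor:
    """Sum of sqrt(diff^2 + eps^2) over all elements."""
    if eps <= 0:
        raise ValueError("eps must be strictly positive")
    _check_shapes(a, b)
    return (_as_tensor(a) - _as_tensor(b)).sum_charbonnier(eps)


def loss_identity(G, F, batch_lt, batch_ft) -> Tensor:
    _check_shapes(batch_lt, batch_ft)
    ft = _as_tensor(batch_ft)
    lt = _as_tensor(batch_lt)
    return (G(ft) - ft).sum_abs() + (F(lt) - lt).sum_abs()


def loss_image_prior(G, batch_lt) -> Tensor:
    lt = _as_tensor(batch_lt)
    return (G(lt) - lt).sum_abs()


def loss_reconstruction(G, batch_lt, batch_ft) -> Tensor:
    _check_shapes(batch_lt, batch_ft)
    lt = _as_tensor(batch_lt)
    ft = _as_tensor(batch_ft)
    n = lt.data.shape[0]
    return (G(lt) - ft).sum_abs() * (1.0 / n)


def loss_cycle(G, F, batch_lt, batch_ft) -> Tensor:
    _check_shapes(batch_lt, batch_ft)
    lt = _as_tensor(batch_lt)
    ft = _as_tensor(batch_ft)
    return (F(G(lt)) - lt).sum_abs() + (G(F(ft)) - ft).sum_abs()


def loss_adversarial(discriminator, samples, side: str) -> Tensor:
    """Least-squares GAN objective.

    side='generator': mean (D(fake) - 1)^2 over the fake ``samples``;
    side='discriminator': 0.5 * [mean (D(real) - 1)^2 + mean D(fake)^2]
    with ``samples = (real, fake)``.
    """
    if side == "generator":
        d = discriminator(_as_tensor(samples))
        return (d - Tensor(np.ones(d.data.shape))).mean_sq()
    if side == "discriminator":
        real, fake = samples
        d_real = discriminator(_as_tensor(real))
        d_fake = discriminator(_as_tensor(fake))
        return ((d_real - Tensor(np.ones(d_real.data.shape))).mean_sq()
                + d_fake.mean_sq()) * 0.5
    raise ValueError("side must be 'generator' or 'discriminator'")
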