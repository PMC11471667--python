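"""Model zoo: architecture accounting, baseline, sampling plumbing, losses."""

import numpy as np
import pytest

from petbench.models import (LossConfig, ModelConfig, TinyResNet,
                             build_discriminator, build_generator,
                             build_patch_discriminator,
                             build_resnet_generator, build_unet_generator,
                             chunk_starts, chunk_volume, count_parameters,
                             gaussian_denoise, loss_adversarial,
                             loss_charbonnier, loss_cycle, loss_identity,
                             loss_image_prior, loss_l1, loss_reconstruction,
                             residual_wrap, stack_slices, tune_gaussian)
from petbench.models.autograd import Tensor, conv_nd
from petbench.models.layers import Conv
from petbench.types import PETVolume


class TestArchitectureCounts:
    def test_unet_generator_parameter_count(self):
        # analytic layer-by-layer count of the 256-resolution U-Net
        spec = build_unet_generator(1, 1)
        assert count_parameters(spec) == 54_407_809
        assert round(count_parameters(spec) / 1e6, 1) == 54.4

    def test_paired_input_patch_discriminator_count(self):
        spec = build_patch_discriminator(in_ch=2)
        assert count_parameters(spec) == 2_764_609
        assert round(count_parameters(spec) / 1e6, 1) == 2.8

    def test_resnet_generator_builds_at_base_width_64(self):
        spec = build_resnet_generator(1, 1, base=64)
        # encoder-heavy down/up generator, ~11.4 M at width 64
        assert 10e6 < count_parameters(spec) < 13e6

    def test_single_small_conv_count(self):
        conv = Conv(1, 8, 3, bias=True)
        assert sum(p.data.size for p in conv.parameters()) == 80  # 8*9 + 8

    def test_inconsistent_grid_rejected(self):
        with pytest.raises(ValueError):
            build_unet_generator(1, 1, input_size=192)  # 192 % 256 != 0

    def test_count_is_stable_across_runs(self):
        c1 = count_parameters(build_unet_generator(1, 1))
        c2 = count_parameters(build_unet_generator(1, 1))
        assert c1 == c2

    def test_model_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(channels=2)  # must be odd (2k+1)
        with pytest.raises(ValueError):
            ModelConfig(width=2)
        cfg = ModelConfig(tier="tiny", width=8, channels=3)
        net = build_generator(cfg)
        assert isinstance(net, TinyResNet)
        assert count_parameters(net) == net.n_parameters()


class TestGaussianBaseline:
    def _vol(self, values, meta):
        return PETVolume(values, (3.27, 2.73, 2.73), meta)

    def test_sigma_zero_is_identity(self, meta):
        rng = np.random.default_rng(0)
        vol = self._vol(rng.uniform(size=(4, 12, 12)), meta)
        out = gaussian_denoise(vol, 0.0)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_unit_impulse_gives_normalized_kernel(self, meta):
        values = np.zeros((9, 21, 21))
        values[4, 10, 10] = 1.0
        out = gaussian_denoise(self._vol(values, meta), 2.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)
        # kernel is maximal at the impulse and symmetric in-plane
        assert out.values[4, 10, 10] == out.values.max()
        np.testing.assert_allclose(out.values[4, 10, :],
                                   out.values[4, 10, ::-1], atol=1e-12)

    def test_constant_volume_unchanged(self, meta):
        vol = self._vol(np.full((4, 16, 16), 3.0), meta)
        np.testing.assert_allclose(gaussian_denoise(vol, 3.0).values, 3.0,
                                   atol=1e-6)

    def test_negative_sigma_rejected(self, meta):
        with pytest.raises(ValueError):
            gaussian_denoise(self._vol(np.zeros((2, 8, 8)), meta), -1.0)

    def test_noiseless_pairs_tune_to_zero(self, meta):
        rng = np.random.default_rng(1)
        ft = self._vol(rng.uniform(0, 5, size=(3, 16, 16)), meta)
        sigma, curve = tune_gaussian([(ft, ft)])
        assert sigma == 0.0
        assert curve[0.0] == min(curve.values())

    def test_tuned_sigma_is_curve_argmin_and_deterministic(self, meta):
        rng = np.random.default_rng(2)
        ft_vals = rng.uniform(0, 5, size=(3, 24, 24))
        lt_vals = np.clip(ft_vals + rng.normal(0, 1.0, ft_vals.shape), 0,
                          None)
        pair = [(self._vol(lt_vals, meta), self._vol(ft_vals, meta))]
        s1, curve1 = tune_gaussian(pair)
        s2, curve2 = tune_gaussian(pair)
        assert s1 == s2 and curve1 == curve2
        assert curve1[s1] == min(curve1.values())

    def test_empty_validation_set_rejected(self):
        with pytest.raises(ValueError):
            tune_gaussian([])


class TestSampling:
    def test_k_zero_returns_single_channel_slices(self):
        v = np.random.default_rng(0).uniform(size=(5, 6, 6))
        s = stack_slices(v, 0)
        assert s.shape == (5, 1, 6, 6)
        np.testing.assert_array_equal(s[:, 0], v)

    def test_replicate_padding_at_boundaries(self):
        v = np.arange(5.0)[:, None, None] * np.ones((1, 2, 2))
        s = stack_slices(v, 2)
        assert s.shape == (5, 5, 2, 2)
        np.testing.assert_array_equal(s[0, :, 0, 0], [0, 0, 0, 1, 2])
        np.testing.assert_array_equal(s[4, :, 0, 0], [2, 3, 4, 4, 4])
        # central channel is the slice itself
        np.testing.assert_array_equal(s[:, 2], v)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            stack_slices(np.zeros((3, 4, 4)), 3)

    def test_chunking_examples(self):
        assert chunk_starts(64, 32, 0) == [0, 32]
        assert chunk_starts(40, 32, 16) == [0, 8]

    def test_identity_model_round_trip(self):
        v = np.random.default_rng(1).uniform(size=(40, 6, 6))
        chunks, reassemble = chunk_volume(v, chunk=32, overlap=16)
        np.testing.assert_allclose(reassemble(chunks), v)

    def test_short_volume_is_padded_then_cropped(self):
        v = np.random.default_rng(2).uniform(size=(10, 4, 4))
        chunks, reassemble = chunk_volume(v, chunk=32)
        assert chunks[0].shape[0] == 32
        np.testing.assert_allclose(reassemble(chunks), v)

    def test_residual_wrap_zero_network_is_identity(self):
        den = residual_wrap(lambda x: np.zeros_like(x))
        v = np.random.default_rng(3).uniform(size=(4, 4))
        np.testing.assert_array_equal(den(v), v)

    def test_residual_wrap_perfect_residual_restores(self):
        lt = np.ones((4, 4))
        ft = np.full((4, 4), 2.0)
        den = residual_wrap(lambda x: ft - lt)
        np.testing.assert_array_equal(den(lt), ft)

    def test_residual_wrap_rejects_shape_change(self):
        den = residual_wrap(lambda x: x[:2])
        with pytest.raises(ValueError):
            den(np.zeros((4, 4)))


class TestLosses:
    def test_identity_maps_zero_identity_prior_cycle(self):
        rng = np.random.default_rng(0)
        lt = rng.uniform(size=(2, 1, 6, 6))
        ft = rng.uniform(size=(2, 1, 6, 6))
        ident = lambda t: t
        assert loss_identity(ident, ident, lt, ft).item() == 0.0
        assert loss_image_prior(ident, lt).item() == 0.0
        assert loss_cycle(ident, ident, lt, ft).item() == 0.0

    def test_constant_offset_image_prior(self):
        lt = np.random.default_rng(1).uniform(size=(3, 1, 4, 4))
        c = 0.25
        shift = lambda t: t + Tensor(np.full(t.data.shape, c))
        m = 16  # voxels per sample
        assert loss_image_prior(shift, lt).item() == pytest.approx(
            3 * m * c)

    def test_charbonnier_at_zero_difference(self):
        a = np.random.default_rng(2).uniform(size=(2, 1, 5, 5))
        eps = 1e-3
        assert loss_charbonnier(a, a, eps).item() == pytest.approx(
            a.size * eps)

    def test_reconstruction_is_per_sample_mean_of_l1_norms(self):
        lt = np.zeros((4, 1, 3, 3))
        ft = np.full((4, 1, 3, 3), 2.0)
        ident = lambda t: t
        assert loss_reconstruction(ident, lt, ft).item() == pytest.approx(
            9 * 2.0)  # ||0 - 2||_1 per sample = 18, averaged over samples

    def test_lsgan_objective_values(self):
        fake = np.zeros((2, 1, 4, 4))
        real = np.ones((2, 1, 4, 4))
        d_half = lambda t: Tensor(np.full((2, 1, 1, 1), 0.5))
        g = loss_adversarial(d_half, fake, "generator")
        assert g.item() == pytest.approx(0.25)  # (0.5 - 1)^2
        d = loss_adversarial(d_half, (real, fake), "discriminator")
        assert d.item() == pytest.approx(0.5 * (0.25 + 0.25))

    def test_total_objective_is_weighted_sum_of_parts(self):
        rng = np.random.default_rng(3)
        lt = rng.uniform(size=(2, 1, 6, 6))
        ft = rng.uniform(size=(2, 1, 6, 6))
        cfg = LossConfig()
        g_map = lambda t: t + Tensor(np.full(t.data.shape, 0.1))
        f_map = lambda t: t * 0.9
        parts = {
            "cycle": loss_cycle(g_map, f_map, lt, ft).item(),
            "identity": loss_identity(g_map, f_map, lt, ft).item(),
            "image_prior": loss_image_prior(g_map, lt).item(),
            "reconstruction": loss_reconstruction(g_map, lt, ft).item(),
        }
        total = sum(getattr(cfg, k) * v for k, v in parts.items())
        recomposed = (cfg.cycle * parts["cycle"]
                      + cfg.identity * parts["identity"]
                      + cfg.image_prior * parts["image_prior"]
                      + cfg.reconstruction * parts["reconstruction"])
        assert total == pytest.approx(recomposed)
        assert cfg.identity == 2.2 and cfg.image_prior == 9.2
        assert cfg.reconstruction == 9.2 and cfg.pix2pix_distance == 10.0

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(identity=-1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss_l1(np.zeros((2, 2)), np.zeros((3, 3)))


class TestAutograd:
    @pytest.mark.parametrize("nd,stride", [(2, 1), (2, 2), (3, 1)])
    def test_conv_gradients_match_finite_differences(self, nd, stride):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 3) + (6,) * nd), requires_grad=True)
        w = Tensor(rng.normal(size=(4, 3) + (3,) * nd), requires_grad=True)
        b = Tensor(rng.normal(size=4), requires_grad=True)

        def f():
            return conv_nd(x, w, b, stride=stride, padding=1).sum_sq()

        f().backward()
        eps = 1e-6
        for t in (x, w, b):
            idx = tuple(rng.integers(0, s) for s in t.data.shape)
            orig = t.data[idx]
            t.data[idx] = orig + eps
            hi = f().item()
            t.data[idx] = orig - eps
            lo = f().item()
            t.data[idx] = orig
            num = (hi - lo) / (2 * eps)
            assert t.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_residual_net_init_is_near_identity(self):
        # small random weights: wrapped output stays close to the input
        net = TinyResNet(1, width=8, depth=1, seed=0)
        x = np.random.default_rng(1).uniform(size=(2, 1, 8, 8))
        out = net(Tensor(x)).data + x
        assert np.abs(out - x).mean() < 0.05
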