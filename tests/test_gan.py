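"""GAN components: loss formulas, R1 penalty, FID, checkpoint selection,
and the micro training loop's contracts."""

import numpy as np
import pytest

from genscreen._autodiff import DTYPE, Tensor
from genscreen.gan import (Checkpoint, Discriminator, Generator,
                           RandomConvFeatures, StyleGan, fid,
                           nonsaturating_losses, r1_penalty,
                           select_checkpoint, train_gan)
from genscreen.synthdata import DatasetManifest
import pandas as pd


class TestLosses:
    def test_zero_logits(self):
        g, d = nonsaturating_losses(np.zeros(4), np.zeros(4))
        assert d.data == pytest.approx(2 * np.log(2), rel=1e-5)
        assert g.data == pytest.approx(np.log(2), rel=1e-5)

    def test_confident_discriminator_limit(self):
        g, d = nonsaturating_losses(np.full(4, 30.0), np.full(4, -30.0))
        assert d.data == pytest.approx(0.0, abs=1e-6)

    def test_matches_scalar_softplus_arithmetic(self):
        def sp(x):
            return np.logaddexp(0.0, x)

        real = np.array([1.0, -1.0])
        fake = np.array([0.0])
        g, d = nonsaturating_losses(real, fake)
        assert d.data == pytest.approx(sp(-real).mean() + sp(fake).mean(),
                                       rel=1e-6)
        assert g.data == pytest.approx(sp(-fake).mean(), rel=1e-6)

    def test_property_on_random_logits(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            real = rng.normal(0, 3, rng.integers(1, 10))
            fake = rng.normal(0, 3, rng.integers(1, 10))
            g, d = nonsaturating_losses(real, fake)
            d_ref = np.logaddexp(0, -real).mean() + np.logaddexp(0, fake).mean()
            g_ref = np.logaddexp(0, -fake).mean()
            assert d.data == pytest.approx(d_ref, rel=1e-4)
            assert g.data == pytest.approx(g_ref, rel=1e-4)


class TestR1Penalty:
    def test_constant_discriminator_zero(self):
        def disc(x):
            return (x * 0.0).sum(axis=(1, 2, 3), keepdims=False).reshape(-1, 1)

        batch = np.random.default_rng(0).random((3, 1, 4, 4))
        assert float(r1_penalty(disc, batch, 5.0).data) == 0.0

    def test_linear_discriminator_analytic_value(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            wvec = rng.standard_normal(16).astype(DTYPE)

            def disc(x, wvec=wvec):
                flat = x.reshape(x.shape[0], 16)
                return flat @ Tensor(wvec.reshape(16, 1))

            batch = rng.random((4, 1, 4, 4)).astype(DTYPE)
            gamma = float(rng.uniform(0.5, 10))
            expected = gamma / 2.0 * float(np.sum(wvec.astype(np.float64) ** 2))
            got = float(r1_penalty(disc, batch, gamma).data)
            assert got == pytest.approx(expected, rel=1e-4)

    def test_gamma_zero_kills_penalty(self):
        disc = Discriminator(resolution=16, in_channels=1, seed=0)
        batch = np.random.default_rng(2).random((2, 1, 16, 16))
        assert float(r1_penalty(disc, batch, 0.0).data) == 0.0

    def test_non_tensor_discriminator_rejected(self):
        with pytest.raises(TypeError):
            r1_penalty(lambda x: np.zeros((2, 1)), np.zeros((2, 1, 4, 4)), 1.0)


class TestFid:
    def test_identical_sets_zero(self):
        feats = np.random.default_rng(0).random((20, 8))
        assert fid(feats, feats) == 0.0

    def test_unit_shift_unit_variance_closed_form(self):
        # exact sample moments: mean 0/1, variance 1 -> FID = 1
        a = np.array([[-np.sqrt(0.5)], [np.sqrt(0.5)]])
        b = a + 1.0
        assert fid(a, b) == pytest.approx(1.0, abs=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((30, 5)), rng.random((40, 5))
        assert fid(a, b) == pytest.approx(fid(b, a), rel=1e-8)

    def test_gaussian_closed_form_on_synthetic_moments(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            mu1, mu2 = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
            A = rng.normal(0, 1, (3, 3))
            s1 = A @ A.T + np.eye(3)
            B = rng.normal(0, 1, (3, 3))
            s2 = B @ B.T + np.eye(3)
            x1 = rng.multivariate_normal(mu1, s1, 4000)
            x2 = rng.multivariate_normal(mu2, s2, 4000)
            from scipy.linalg import sqrtm

            m1, m2 = x1.mean(0), x2.mean(0)
            c1 = np.cov(x1, rowvar=False)
            c2 = np.cov(x2, rowvar=False)
            expect = float(
                np.sum((m1 - m2) ** 2)
                + np.trace(c1 + c2 - 2 * np.real(sqrtm(c1 @ c2)))
            )
            assert fid(x1, x2) == pytest.approx(expect, rel=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fid(np.zeros((4, 3)), np.zeros((4, 2)))


class TestSelectCheckpoint:
    def _ckpt(self, step, value):
        return Checkpoint(step=step, fid=value, state={}, arch={})

    def test_argmin(self):
        cs = [self._ckpt(1, 30), self._ckpt(2, 12), self._ckpt(3, 19)]
        assert select_checkpoint(cs).step == 2

    def test_tie_prefers_earlier(self):
        cs = [self._ckpt(1, 12.0), self._ckpt(2, 12.0)]
        assert select_checkpoint(cs).step == 1

    def test_single_and_empty(self):
        only = self._ckpt(5, 3.0)
        assert select_checkpoint([only]) is only
        with pytest.raises(ValueError):
            select_checkpoint([])


class TestGeneratorContract:
    def test_output_shape_and_differentiability(self):
        gen = Generator(resolution=16, dim_z=8, dim_w=8, seed=0)
        w = Tensor(np.random.default_rng(0).standard_normal((2, 8)).astype(DTYPE),
                   requires_grad=True)
        img = gen.synthesis(w)
        assert img.shape == (2, 3, 16, 16)
        from genscreen._autodiff import grad

        g, = grad((img ** 2.0).sum(), [w])
        assert np.isfinite(g.data).all() and np.abs(g.data).sum() > 0

    def test_state_dict_roundtrip(self):
        gen = Generator(resolution=16, dim_z=8, dim_w=8, seed=0)
        state = gen.state_dict()
        gen2 = Generator(resolution=16, dim_z=8, dim_w=8, seed=99)
        gen2.load_state_dict(state)
        z = np.random.default_rng(0).standard_normal((3, 8)).astype(DTYPE)
        np.testing.assert_array_equal(gen.synthesize01(gen.map_latents(z)),
                                      gen2.synthesize01(gen2.map_latents(z)))


class TestTraining:
    def test_refuses_normals_in_upstream(self):
        frame = pd.DataFrame(
            dict(image_id=["a", "b"], label=[1, 0], split=["upstream"] * 2)
        )
        manifest = DatasetManifest(frame=frame)
        from genscreen.gan import GanTrainConfig

        with pytest.raises(ValueError, match="diseased-only"):
            train_gan(manifest, GanTrainConfig(total_steps=1),
                      images=np.zeros((2, 3, 32, 32), dtype=np.float32))

    def test_first_steps_deterministic_given_seed(self):
        X = np.random.default_rng(0).random((24, 3, 32, 32)).astype(np.float32)
        runs = []
        for _ in range(2):
            est = StyleGan(total_steps=3, fid_interval=100, seed=42)
            est.fit(X)
            runs.append(est.loss_trace_)
        assert runs[0] == runs[1]

    def test_config_echo_contains_r1_coefficient(self):
        est = StyleGan(total_steps=1, fid_interval=10)
        assert est.get_params()["r1_gamma"] == 6.5536

    def test_micro_run_records_checkpoints_and_fid_trend(self, gan_result):
        result = gan_result
        assert len(result.checkpoints) >= 2
        fids = [f for _, f in result.fid_trace]
        best_so_far = np.minimum.accumulate(fids)
        assert (np.diff(best_so_far) <= 1e-12).all()

    def test_trained_generator_mean_image_closer_than_untrained(
        self, gan_result, upstream_images
    ):
        rng = np.random.default_rng(0)
        trained = gan_result.generator.sample01(64, rng)
        untrained = Generator(resolution=32, seed=123).sample01(
            64, np.random.default_rng(0)
        )
        target = upstream_images.mean(axis=0)
        d_trained = np.linalg.norm(trained.mean(axis=0) - target)
        d_untrained = np.linalg.norm(untrained.mean(axis=0) - target)
        assert d_trained < d_untrained


def test_random_conv_features_are_deterministic():
    imgs = np.random.default_rng(0).random((4, 3, 32, 32))
    a = RandomConvFeatures()(imgs)
    b = RandomConvFeatures()(imgs)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (4, 64)
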