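"""Gradient operators, structure-tensor windowing against a direct-summation
oracle, orientation/coherency closed forms, equivariance and renders."""

import numpy as np
import pytest
from scipy import ndimage

from orientfilm import synthgen as sg
from orientfilm import tensorfield as tf
from conftest import angdiff, circular_mean_deg


class TestGradient:
    @pytest.mark.parametrize("op", tf.GRADIENT_OPERATORS)
    def test_constant_image_zero_gradient(self, op):
        g = tf.gradient(np.full((32, 32), 7.0), operator=op)
        assert np.abs(g.fx1).max() < 1e-9 and np.abs(g.fx2).max() < 1e-9

    def test_linear_ramp_central_difference(self):
        x = np.tile(np.arange(32.0), (32, 1))
        g = tf.gradient(x, operator="finite_difference")
        np.testing.assert_allclose(g.fx1[1:-1, 1:-1], 1.0)
        np.testing.assert_allclose(g.fx2[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_riesz_pure_x_sinusoid_has_no_y_component(self):
        x = np.tile(np.arange(64.0), (64, 1))
        img = np.cos(2 * np.pi * x * 4 / 64)  # integer cycles: periodic
        g = tf.gradient(img, operator="riesz")
        assert np.abs(g.fx2).max() <= 1e-6 * np.abs(g.fx1).max()

    def test_unknown_operator_lists_valid_names(self):
        with pytest.raises(ValueError, match="riesz"):
            tf.gradient(np.zeros((8, 8)), operator="sobel")

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            tf.gradient(np.zeros((2, 5)))


class TestStructureTensor:
    def test_zero_gradient_zero_tensor(self):
        g = tf.GradientField(np.zeros((16, 16)), np.zeros((16, 16)), "riesz")
        t = tf.structure_tensor(g, window_sigma=3.0)
        assert t.jxx.max() == t.jxy.max() == t.jyy.max() == 0.0

    def test_constant_gradient_closed_form(self):
        a, b = 2.0, -3.0
        g = tf.GradientField(np.full((24, 24), a), np.full((24, 24), b), "riesz")
        t = tf.structure_tensor(g, window_sigma=2.0)
        np.testing.assert_allclose(t.jxx, a * a, rtol=1e-12)
        np.testing.assert_allclose(t.jxy, a * b, rtol=1e-12)
        np.testing.assert_allclose(t.jyy, b * b, rtol=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        fx = rng.standard_normal((32, 32))
        fy = rng.standard_normal((32, 32))
        sigma = 2.5
        t = tf.structure_tensor(tf.GradientField(fx, fy, "riesz"), sigma)
        # oracle: explicit normalized Gaussian window sum with symmetric padding
        radius = int(4.0 * sigma + 0.5)  # scipy's default truncate=4.0
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        k /= k.sum()
        w2d = np.outer(k, k)

        def oracle(prod):
            pad = np.pad(prod, radius, mode="symmetric")
            out = np.empty_like(prod)
            for i in range(prod.shape[0]):
                for j in range(prod.shape[1]):
                    out[i, j] = (pad[i:i + 2 * radius + 1,
                                     j:j + 2 * radius + 1] * w2d).sum()
            return out

        np.testing.assert_allclose(t.jxx, oracle(fx * fx), atol=1e-6)
        np.testing.assert_allclose(t.jxy, oracle(fx * fy), atol=1e-6)
        np.testing.assert_allclose(t.jyy, oracle(fy * fy), atol=1e-6)

    def test_nonpositive_sigma_rejected(self):
        g = tf.GradientField(np.zeros((8, 8)), np.zeros((8, 8)), "riesz")
        with pytest.raises(ValueError):
            tf.structure_tensor(g, window_sigma=0.0)


class TestOrientationCoherency:
    def test_isotropic_tensor_zero_coherency_undefined_theta_at_zero_energy(self):
        t = tf.StructureTensorField(np.ones((8, 8)), np.zeros((8, 8)),
                                    np.ones((8, 8)), 2.0)
        o = tf.orientation_and_coherency(t)
        np.testing.assert_allclose(o.coherency, 0.0, atol=1e-12)
        z = tf.StructureTensorField(*(np.zeros((8, 8)),) * 3, 2.0)
        oz = tf.orientation_and_coherency(z)
        assert np.isnan(oz.theta).all() and (oz.coherency == 0).all()

    def test_vertical_stripes_theta_90_full_coherency(self):
        x = np.tile(np.arange(128.0), (128, 1))
        img = np.cos(2 * np.pi * x / 16)
        o, _ = tf.orientation_field(img, operator="riesz", window_sigma=8.0)
        inner = (slice(20, -20), slice(20, -20))
        assert angdiff(circular_mean_deg(o.theta[inner]), 90.0) < 0.5
        assert o.coherency[inner].min() > 0.98

    @pytest.mark.parametrize("angle", [0.0, 30.0, 45.0, 60.0, 90.0, 135.0])
    @pytest.mark.parametrize("op", ["riesz", "gaussian"])
    def test_grating_angle_recovery(self, angle, op):
        img = sg.gen_oriented_texture((256, 256), angle, 1.0, 16.0, seed=1)
        o, _ = tf.orientation_field(img, operator=op, window_sigma=8.0)
        assert angdiff(circular_mean_deg(o.theta), angle) <= 1.0
        assert o.coherency.mean() >= 0.95

    def test_coherency_matches_eigenvalue_contrast(self):
        rng = np.random.default_rng(2)
        img = rng.standard_normal((48, 48))
        o, t = tf.orientation_field(img, window_sigma=3.0)
        J = np.moveaxis(np.array([[t.jxx, t.jxy], [t.jxy, t.jyy]]), (0, 1), (2, 3))
        evals = np.linalg.eigvalsh(J)  # ascending
        c_eig = (evals[..., 1] - evals[..., 0]) / (evals[..., 1] + evals[..., 0])
        np.testing.assert_allclose(o.coherency, c_eig, atol=1e-9)

    def test_theta_invariant_to_affine_intensity(self):
        img = sg.gen_oriented_texture((128, 128), 70.0, 0.9, 16.0, seed=3)
        o1, _ = tf.orientation_field(img, window_sigma=8.0)
        o2, _ = tf.orientation_field(3.7 * img + 50.0, window_sigma=8.0)
        np.testing.assert_allclose(o1.theta, o2.theta, atol=1e-6)

    @pytest.mark.parametrize("delta", [15.0, 30.0, 45.0])
    @pytest.mark.parametrize("op", ["riesz", "gaussian"])
    def test_rotation_equivariance(self, delta, op):
        img = sg.gen_oriented_texture((256, 256), 20.0, 1.0, 16.0, seed=4)
        rot = ndimage.rotate(img, delta, reshape=False, order=3, mode="reflect")
        o, _ = tf.orientation_field(rot, operator=op, window_sigma=8.0)
        inner = (slice(64, -64), slice(64, -64))  # rotation-artifact-free core
        got = circular_mean_deg(o.theta[inner])
        assert angdiff(got, (20.0 + delta) % 180.0) <= 2.0

    def test_riesz_scale_invariance_at_fixed_sigma_ratio(self):
        # doubling the wavelength and the window together leaves theta and C
        # (essentially) unchanged
        stats = []
        for lam, sigma in ((16.0, 8.0), (32.0, 16.0)):
            img = sg.gen_oriented_texture((256, 256), 30.0, 1.0, lam, seed=5)
            o, _ = tf.orientation_field(img, operator="riesz", window_sigma=sigma)
            inner = (slice(32, -32), slice(32, -32))
            stats.append((circular_mean_deg(o.theta[inner]),
                          float(o.coherency[inner].mean())))
        assert angdiff(stats[0][0], stats[1][0]) <= 0.5
        assert abs(stats[0][1] - stats[1][1]) <= 0.02

    def test_isotropic_noise_low_coherency_across_seeds(self):
        for seed in range(5):
            img = sg.gen_oriented_texture((256, 256), 0.0, 0.0, 16.0, seed=seed)
            o, _ = tf.orientation_field(img, window_sigma=8.0)
            assert o.coherency.mean() <= 0.3


class TestRenders:
    def test_hsb_channels(self, grating_45):
        o, _ = tf.orientation_field(grating_45, window_sigma=8.0)
        rgb = tf.render_hsb(o, grating_45)
        assert rgb.dtype == np.uint8 and rgb.shape == (256, 256, 3)
        # dominant hue: 45 deg -> hue 0.25 -> green-ish; just check a single
        # dominant hue bin
        import matplotlib.colors as mc
        hsv = mc.rgb_to_hsv(rgb / 255.0)
        hist, _ = np.histogram(hsv[..., 0], bins=18, range=(0, 1))
        assert hist.max() / hist.sum() >= 0.8

    def test_zero_coherency_renders_gray(self):
        o = tf.OrientationField(theta=np.full((8, 8), np.nan),
                                coherency=np.zeros((8, 8)),
                                energy=np.zeros((8, 8)))
        rgb = tf.render_hsb(o, np.tile(np.arange(8.0), (8, 1)))
        assert (rgb[..., 0] == rgb[..., 1]).all() and (rgb[..., 1] == rgb[..., 2]).all()

    def test_coherency_map_extremes(self):
        o1 = tf.OrientationField(np.zeros((4, 4)), np.ones((4, 4)), np.ones((4, 4)))
        o0 = tf.OrientationField(np.zeros((4, 4)), np.zeros((4, 4)), np.ones((4, 4)))
        assert (tf.render_coherency(o1) == 255).all()
        assert (tf.render_coherency(o0) == 0).all()

    def test_mosaic_coherency_contrast(self):
        iso = sg.gen_oriented_texture((128, 128), 0.0, 0.0, 16.0, seed=6)
        ani = sg.gen_oriented_texture((128, 128), 60.0, 0.95, 16.0, seed=6)
        img = np.hstack([iso, ani])
        o, _ = tf.orientation_field(img, window_sigma=8.0)
        cmap = tf.render_coherency(o)
        assert cmap[:, 160:].mean() > cmap[:, :96].mean()
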