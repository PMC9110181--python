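"""Coordinate network: architecture, initialization, gradients, rendering."""

import dataclasses

import numpy as np
import pytest

from neurec.model import INRModel, LatentTable, ModelConfig, condition, init_model, render


class TestArchitecture:
    def test_default_config_matches_stated_architecture(self):
        cfg = ModelConfig()
        assert (cfg.n_blocks, cfg.hidden_width, cfg.latent_dim, cfg.out_dim) == (6, 256, 16, 1)
        m = init_model(cfg, seed=0)
        assert m.theta["W_in"].shape == (2, 256)
        for k in range(6):
            assert m.theta[f"W_{k}"].shape == (256, 256)
        assert m.theta["Wc1"].shape == (16, 256)
        assert m.theta["Wc2"].shape == (256, 256)
        assert m.theta["W_out"].shape == (256, 1)

    def test_parameter_count_deterministic_in_config(self):
        a = init_model(ModelConfig(), seed=0)
        b = init_model(ModelConfig(), seed=99)
        assert a.n_parameters == b.n_parameters

    def test_same_seed_identical_parameters(self, tiny_model_config):
        a = init_model(tiny_model_config, seed=3)
        b = init_model(tiny_model_config, seed=3)
        for k in a.theta:
            np.testing.assert_array_equal(a.theta[k], b.theta[k])

    def test_init_ranges(self):
        cfg = ModelConfig(hidden_width=64)
        m = init_model(cfg, seed=1)
        assert np.abs(m.theta["W_in"]).max() <= 1.0 / cfg.in_dim
        bound = np.sqrt(6.0 / 64) / cfg.sine_omega
        for k in range(cfg.n_blocks):
            assert np.abs(m.theta[f"W_{k}"]).max() <= bound

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(n_blocks=0)
        with pytest.raises(ValueError):
            ModelConfig(sine_omega=0.0)
        with pytest.raises(ValueError):
            ModelConfig(in_dim=4)


class TestConditioning:
    def test_feature_length_is_hidden_width(self):
        m = init_model(ModelConfig(), seed=0)
        c = condition(np.zeros(16), m)
        assert c.shape == (256,)

    def test_zeroed_weights_ignore_latent(self, tiny_model_config, rng):
        m = init_model(tiny_model_config, seed=2)
        m.theta["Wc1"][:] = 0.0
        m.theta["Wc2"][:] = 0.0
        c1 = condition(rng.normal(size=4), m)
        c2 = condition(rng.normal(size=4), m)
        np.testing.assert_array_equal(c1, c2)
        coords = rng.uniform(-1, 1, (7, 2))
        np.testing.assert_array_equal(
            m.forward(rng.normal(size=4), coords), m.forward(rng.normal(size=4), coords)
        )

    def test_latent_changes_output(self, tiny_model_config, rng):
        m = init_model(tiny_model_config, seed=2)
        coords = rng.uniform(-1, 1, (7, 2))
        out1 = m.forward(rng.normal(size=4), coords)
        out2 = m.forward(rng.normal(size=4), coords)
        assert not np.array_equal(out1, out2)

    def test_finite_for_unit_latents(self, tiny_model_config, rng):
        m = init_model(tiny_model_config, seed=2)
        for _ in range(10):
            e = rng.normal(size=4)
            e /= np.linalg.norm(e)
            assert np.all(np.isfinite(condition(e, m)))

    def test_latent_length_mismatch_rejected(self, tiny_model_config):
        m = init_model(tiny_model_config, seed=0)
        with pytest.raises(ValueError):
            m.forward(np.zeros(5), np.zeros((3, 2)))


class TestForward:
    def test_single_point_scalar_output(self, tiny_model_config):
        m = init_model(tiny_model_config, seed=0)
        out = m.forward(np.zeros(4), np.array([[0.1, -0.2]]))
        assert out.shape == (1, 1)

    def test_bit_identical_repeat(self, tiny_model_config, rng):
        m = init_model(tiny_model_config, seed=0)
        coords = rng.uniform(-1, 1, (11, 2))
        e = rng.normal(size=4)
        np.testing.assert_array_equal(m.forward(e, coords), m.forward(e, coords))

    def test_coordinate_dim_mismatch_rejected(self, tiny_model_config):
        m = init_model(tiny_model_config, seed=0)
        with pytest.raises(ValueError):
            m.forward(np.zeros(4), np.zeros((3, 3)))


class TestGradients:
    def test_autodiff_matches_central_differences(self, tiny_model_config, rng):
        """Reverse-mode gradients vs the finite-difference oracle (1e-4 rel)."""
        m = init_model(tiny_model_config, seed=0)
        coords = rng.uniform(-1, 1, (5, 2))
        latent = rng.normal(0, 0.5, 4)
        g_out = rng.normal(size=(5, 1))
        grads, g_lat, g_crd = m.gradients(latent, coords, g_out)

        def objective():
            return float((m.forward(latent, coords) * g_out).sum())

        eps = 1e-6
        for name, arr in m.theta.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                arr[idx] += eps
                up = objective()
                arr[idx] -= 2 * eps
                dn = objective()
                arr[idx] += eps
                fd = (up - dn) / (2 * eps)
                assert abs(fd - grads[name][idx]) <= 1e-4 * max(abs(fd), 1e-8), name
        for i in range(4):
            latent[i] += eps
            up = objective()
            latent[i] -= 2 * eps
            dn = objective()
            latent[i] += eps
            fd = (up - dn) / (2 * eps)
            assert abs(fd - g_lat[i]) <= 1e-4 * max(abs(fd), 1e-8)
        for (r, c) in [(0, 0), (2, 1), (4, 0)]:
            coords[r, c] += eps
            up = objective()
            coords[r, c] -= 2 * eps
            dn = objective()
            coords[r, c] += eps
            fd = (up - dn) / (2 * eps)
            assert abs(fd - g_crd[r, c]) <= 1e-4 * max(abs(fd), 1e-8)


class TestRender:
    def test_multiscale_consistency(self, rng):
        """Downsampled fine render approximates the coarse render (continuity)."""
        m = init_model(ModelConfig(hidden_width=32, n_blocks=3, sine_omega=8.0), seed=5)
        lat = rng.normal(0, 0.5, 16)
        r64 = render(m, lat, 64).values
        r128 = render(m, lat, 128).values
        down = r128.reshape(64, 2, 64, 2).mean(axis=(1, 3))
        rms = np.sqrt(((down - r64) ** 2).mean())
        assert rms < 0.01 * np.sqrt((r64**2).mean())

    def test_render_repeat_identical(self, tiny_model_config):
        m = init_model(tiny_model_config, seed=1)
        np.testing.assert_array_equal(
            render(m, np.zeros(4), 16).values, render(m, np.zeros(4), 16).values
        )

    def test_zero_weights_render_constant_bias(self, tiny_model_config):
        m = init_model(tiny_model_config, seed=1)
        for v in m.theta.values():
            v[:] = 0.0
        m.theta["b_out"][:] = 0.37
        img = render(m, np.zeros(4), 16).values
        np.testing.assert_allclose(img, 0.37)

    def test_total_variation_decreases_with_omega(self):
        """Spatial-coherence prior: on fixed weights, lower omega = smoother."""

        def tv(a):
            return np.abs(np.diff(a, axis=0)).sum() + np.abs(np.diff(a, axis=1)).sum()

        base = init_model(ModelConfig(hidden_width=32, n_blocks=3, sine_omega=30.0), seed=7)
        tvs = []
        for om in (5.0, 10.0, 20.0, 30.0):
            m = INRModel(base.theta, dataclasses.replace(base.config, sine_omega=om))
            tvs.append(tv(render(m, np.zeros(16), 64).values))
        assert all(np.isfinite(tvs))
        assert tvs == sorted(tvs)


def test_latent_table_enforces_uniform_length():
    table = LatentTable()
    table["a"] = np.zeros(16)
    with pytest.raises(ValueError):
        table["b"] = np.zeros(8)
    with pytest.raises(ValueError):
        table["c"] = np.array([np.nan] * 16)
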