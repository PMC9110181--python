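"""Training: schedule, measurement loss, pretraining, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neurec as nr
from neurec.model import ModelConfig, init_model, render
from neurec.training import NormStats, TrainConfig, lr_schedule


class DenseOperator:
    """Explicit-matrix operator stub for loss-oracle and permutation tests."""

    def __init__(self, A, grid_size):
        self.A = A
        self.grid_size = grid_size

    @property
    def n_measurements(self):
        return self.A.shape[0]

    def apply_flat(self, flat):
        return self.A @ flat

    def adjoint_flat(self, vec):
        return self.A.T @ np.real(vec)


class TestSchedule:
    def test_paper_anchor_points(self):
        cfg = TrainConfig()
        assert lr_schedule(0, cfg) == 0.0
        assert lr_schedule(100, cfg) == pytest.approx(1e-4)
        assert lr_schedule(400, cfg) == pytest.approx(5e-5)  # 1e-4 * sqrt(100/400)

    def test_shape_warmup_then_sqrt_decay(self):
        cfg = TrainConfig()
        vals = [lr_schedule(t, cfg) for t in range(0, 2000)]
        peak = max(vals)
        assert peak == pytest.approx(cfg.peak_lr)
        w = cfg.warmup_steps
        assert all(b >= a for a, b in zip(vals[: w + 1], vals[1 : w + 1]))
        assert all(b <= a for a, b in zip(vals[w:], vals[w + 1 :]))
        # continuity at the changeover
        assert abs(lr_schedule(w, cfg) - lr_schedule(w + 1, cfg)) < 1e-6

    def test_rejects_negative_step(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, TrainConfig())

    @settings(deadline=None, derandomize=True)
    @given(
        step=st.integers(min_value=0, max_value=10**6),
        peak=st.floats(min_value=1e-6, max_value=1.0),
        warmup=st.integers(min_value=1, max_value=10_000),
    )
    def test_rate_bounded_by_peak_and_nonnegative(self, step, peak, warmup):
        cfg = TrainConfig(peak_lr=peak, warmup_steps=warmup)
        rate = lr_schedule(step, cfg)
        assert 0.0 <= rate <= peak * (1 + 1e-12)


class TestNormStats:
    def test_requires_positive_std(self):
        with pytest.raises(ValueError):
            NormStats(0.0, 0.0)

    def test_roundtrip(self, rng):
        z = rng.normal(2.0, 3.0, size=50)
        ns = NormStats.from_measurements([z])
        np.testing.assert_allclose(ns.denormalize(ns.normalize(z)), z, atol=1e-12)
        assert ns.normalize(z).mean() == pytest.approx(0.0, abs=1e-12)
        assert ns.normalize(z).std() == pytest.approx(1.0, rel=1e-9)


class TestMeasurementLoss:
    def test_zero_for_consistent_measurement(self, desk_model_config):
        m = init_model(desk_model_config, seed=0)
        lat = np.zeros(16)
        op = nr.RadonOperator(nr.sparse_view_geometry(5, 16), 16)
        z = op.apply_flat(render(m, lat, 16).values.ravel())
        assert nr.measurement_loss(m, lat, op, z, NormStats(0.0, 1.0)) < 1e-20

    def test_matches_dense_matrix_residual(self, small_geometry, tiny_model_config, rng):
        """Loss oracle: ||A vec(yhat) - z||^2 / (M sigma^2) on a 16x16 system."""
        m = init_model(tiny_model_config, seed=4)
        lat = rng.normal(size=4)
        A = nr.operator_matrix(small_geometry, 16)
        op = nr.RadonOperator(small_geometry, 16)
        z = rng.normal(size=A.shape[0])
        ns = NormStats.from_measurements([z])
        got = nr.measurement_loss(m, lat, op, z, ns)
        yhat = render(m, lat, 16).values.ravel()
        want = np.mean((A @ yhat - z) ** 2) / ns.std**2
        assert got == pytest.approx(want, abs=1e-8)

    def test_invariant_to_joint_permutation(self, small_geometry, tiny_model_config, rng):
        m = init_model(tiny_model_config, seed=4)
        lat = rng.normal(size=4)
        A = nr.operator_matrix(small_geometry, 16)
        z = rng.normal(size=A.shape[0])
        perm = rng.permutation(A.shape[0])
        ns = NormStats.from_measurements([z])
        a = nr.measurement_loss(m, lat, DenseOperator(A, 16), z, ns)
        b = nr.measurement_loss(m, lat, DenseOperator(A[perm], 16), z[perm], ns)
        assert a == pytest.approx(b, rel=1e-12)

    def test_geometry_mismatch_rejected(self, tiny_model_config):
        m = init_model(tiny_model_config, seed=0)
        op = nr.RadonOperator(nr.sparse_view_geometry(5, 16), 16)
        with pytest.raises(ValueError):
            nr.measurement_loss(m, np.zeros(4), op, np.zeros(3))


def _tiny_population(n, size=32, views=10, seed=1):
    geom = nr.sparse_view_geometry(views, size)
    op = nr.RadonOperator(geom, size)
    pop = []
    for i in range(n):
        ph = nr.sample_random_phantom(seed, i)
        pop.append((ph.patient_id, op.measure(nr.rasterize(ph, size)).values, op))
    return pop, op


class TestPretrain:
    def test_smoke_loss_drops_tenfold(self):
        """5 small patients, sparse views: joint GLO fit reduces the loss >=10x
        and separates the per-patient latents."""
        pop, _ = _tiny_population(5)
        mc = ModelConfig(hidden_width=32, n_blocks=3, sine_omega=8.0)
        ck = nr.pretrain(pop, TrainConfig(total_steps=2000, seed=1), mc)
        h = ck.loss_history
        assert h[:5].mean() / h[-5:].mean() >= 10.0
        lats = list(ck.latents.values())
        assert not np.array_equal(lats[0], lats[1])

    def test_deterministic(self):
        pop, _ = _tiny_population(3, size=16, views=5)
        mc = ModelConfig(hidden_width=16, n_blocks=2, sine_omega=8.0)
        a = nr.pretrain(pop, TrainConfig(total_steps=100, seed=5), mc)
        b = nr.pretrain(pop, TrainConfig(total_steps=100, seed=5), mc)
        np.testing.assert_array_equal(a.loss_history, b.loss_history)
        for k in a.model.theta:
            np.testing.assert_array_equal(a.model.theta[k], b.model.theta[k])

    def test_rejects_single_patient(self):
        pop, _ = _tiny_population(1, size=16, views=5)
        with pytest.raises(ValueError):
            nr.pretrain(pop, TrainConfig(total_steps=10))


class TestReconstruct:
    def test_dense_views_reach_high_psnr(self, desk_model_config):
        """Well-posed sanity: dense 60-view data, no prior, fits the phantom."""
        size = 32
        op = nr.RadonOperator(nr.sparse_view_geometry(60, size), size)
        truth = nr.canonical_shepp_logan(size)
        z = op.measure(truth).values
        mc = ModelConfig(hidden_width=64, n_blocks=4, sine_omega=30.0)
        img, _ = nr.reconstruct_from_scratch(
            mc, z, op, TrainConfig(total_steps=2000, seed=3), ground_truth=truth
        )
        assert nr.evaluate(img, truth).psnr_db >= 25.0

    def test_zero_steps_returns_initial_render(self, desk_model_config):
        op = nr.RadonOperator(nr.sparse_view_geometry(5, 16), 16)
        z = np.zeros(op.n_measurements)
        img, trace = nr.reconstruct_from_scratch(
            desk_model_config, z, op, TrainConfig(total_steps=0, seed=2)
        )
        m = init_model(desk_model_config, seed=int(np.random.default_rng(2).integers(2**31)))
        np.testing.assert_allclose(img.values, render(m, np.zeros(16), 16).values)
        assert len(trace) == 1

    def test_deterministic(self, desk_model_config):
        op = nr.RadonOperator(nr.sparse_view_geometry(5, 16), 16)
        truth = nr.canonical_shepp_logan(16)
        z = op.measure(truth).values
        runs = [
            nr.reconstruct_from_scratch(
                desk_model_config, z, op, TrainConfig(total_steps=20, seed=9)
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0][0].values, runs[1][0].values)
        np.testing.assert_array_equal(runs[0][1].meas_residual, runs[1][1].meas_residual)

    def test_measurement_length_mismatch_rejected(self, desk_model_config):
        op = nr.RadonOperator(nr.sparse_view_geometry(5, 16), 16)
        with pytest.raises(ValueError):
            nr.reconstruct_from_scratch(
                desk_model_config, np.zeros(3), op, TrainConfig(total_steps=1)
            )


class TestAblation:
    def test_structure_and_progress(self):
        mc = ModelConfig(hidden_width=32, n_blocks=3, sine_omega=8.0)
        res = nr.ablation_experiment(
            4, n_views=10, seed=2, size=32, pretrain_steps=400, recon_steps=120,
            model_config=mc,
        )
        trp = res["with_prior"][1]
        trn = res["without_prior"][1]
        assert len(trp) == len(trn) == 121
        assert trp.image_mse[-1] < trp.image_mse[0]
        assert trn.image_mse[-1] < trn.image_mse[0]

    def test_rejects_held_out_in_training_set(self):
        mc = ModelConfig(hidden_width=16, n_blocks=2, sine_omega=8.0)
        with pytest.raises(ValueError):
            nr.ablation_experiment(
                3, n_views=5, seed=2, size=16, pretrain_steps=4, recon_steps=2,
                model_config=mc, held_out_index=1,
            )
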