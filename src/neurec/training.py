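"""Population pretraining (generative latent optimization) and per-patient
reconstruction by measurement-space fitting.

The objective is the empirical measurement loss

    L(theta, e_i) = (1/M) * || F f_{theta, e_i}(x) - z_i ||^2 / sigma^2

where f is the coordinate network rendered on the operator's pixel grid, F is
the linearized measurement operator, z_i the patient's measurement vector, and
sigma the standard deviation of the measurements over the training samples
(measurements are centered/normalized by training statistics, which cancels
the mean and leaves a 1/sigma^2 scaling of the residual).

Pretraining jointly optimizes the shared weights theta and a per-patient
latent e_i (dimension 16 by default) with Adam, cycling round-robin through
the cohort; the result is a checkpoint carrying theta, the latent table and
the normalization statistics.  Reconstruction of a new patient finetunes theta
from the checkpoint while the latent is drawn randomly and frozen (the
`optimize_latent` flag enables joint latent optimization instead).  The
no-prior ablation starts from a fresh initialization with a zero latent.

The learning rate warms up linearly from 0 to the peak over the first
`warmup_steps` iterations and then decays proportional to the inverse square
root of the step count (Noam schedule), continuous at the changeover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import INRModel, LatentTable, ModelConfig, init_model
from .phantoms import ImageGrid, pixel_centers

__all__ = [
    "TrainConfig",
    "NormStats",
    "FitTrace",
    "Checkpoint",
    "lr_schedule",
    "measurement_loss",
    "pretrain",
    "reconstruct",
    "ablation_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    peak_lr: float = 1e-4
    warmup_steps: int = 100
    total_steps: int = 2000
    batch_rays: int | None = None  # None = full measurement per step
    seed: int = 0
    normalize: bool = True

    def __post_init__(self):
        if self.warmup_steps < 1:
            raise ValueError("warmup_steps must be >= 1")
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive")
        if self.total_steps < 0:
            raise ValueError("total_steps must be >= 0")


@dataclass(frozen=True)
class NormStats:
    mean: float
    std: float

    def __post_init__(self):
        if not self.std > 0:
            raise ValueError("std must be positive")

    @staticmethod
    def from_measurements(measurements) -> "NormStats":
        flat = np.concatenate([np.asarray(z).ravel() for z in measurements])
        mean = complex(flat.mean())
        std = float(np.sqrt(np.mean(np.abs(flat - mean) ** 2)))
        if std == 0.0:
            std = 1.0
        if abs(mean.imag) < 1e-300:
            mean = mean.real
        return NormStats(mean=mean, std=std)

    def normalize(self, z: np.ndarray) -> np.ndarray:
        return (np.asarray(z) - self.mean) / self.std

    def denormalize(self, z_norm: np.ndarray) -> np.ndarray:
        return np.asarray(z_norm) * self.std + self.mean


@dataclass
class FitTrace:
    """Per-iteration record; entry t is the state after t optimizer steps."""

    meas_residual: np.ndarray
    image_mse: np.ndarray | None = None

    def __len__(self):
        return len(self.meas_residual)


@dataclass
class Checkpoint:
    model: INRModel
    latents: LatentTable
    norm_stats: NormStats
    train_patient_ids: tuple = ()
    loss_history: np.ndarray | None = None  # per-step training loss
    version: str = "neurec-ckpt-1"


def lr_schedule(step: int, config: TrainConfig) -> float:
    """rate(t) = peak * min(t / warmup, sqrt(warmup / t)); 0 at t = 0."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if step == 0:
        return 0.0
    w = config.warmup_steps
    return config.peak_lr * min(step / w, np.sqrt(w / step))


class Adam:
    """Plain Adam over a dict of parameter arrays."""

    def __init__(self, shapes: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + self.eps)


def _loss_and_grads(model, latent, operator, z, norm, coords, want_grads=True):
    """Measurement loss and (optionally) gradients w.r.t. theta and latent."""
    out, cache = model.forward(latent, coords, cache=True)
    flat = out[:, 0]
    z = np.asarray(z).ravel()
    resid = (operator.apply_flat(flat) - z) / norm.std
    M = resid.size
    loss = float(np.mean(np.abs(resid) ** 2))
    if not want_grads:
        return loss, None, None, flat
    grad_flat = operator.adjoint_flat(resid) * (2.0 / (M * norm.std))
    grads, grad_latent, _ = model.backward(cache, grad_flat[:, None])
    return loss, grads, grad_latent, flat


def measurement_loss(model, latent, operator, z, norm: NormStats | None = None) -> float:
    """Mean squared residual between F(render) and the normalized measurement."""
    z = np.asarray(z).ravel()
    if z.size != operator.n_measurements:
        raise ValueError("measurement length does not match operator geometry")
    norm = norm or NormStats.from_measurements([z])
    coords = pixel_centers((operator.grid_size,) * model.config.in_dim)
    loss, *_ = _loss_and_grads(model, latent, operator, z, norm, coords, want_grads=False)
    return loss


def pretrain(
    population,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    latent_init_scale: float = 0.01,
) -> Checkpoint:
    """Jointly fit theta and one latent per patient over the cohort.

    ``population`` is a list of (patient_id, measurement, operator) triples;
    both theta and the visited patient's latent receive an Adam update every
    step, cycling round-robin.  Requires >= 2 patients (the interpatient prior
    is undefined for a single patient)."""
    if len(population) < 2:
        raise ValueError("pretraining requires at least 2 patients")
    model_config = model_config or ModelConfig()
    rng = np.random.default_rng(config.seed)
    model = init_model(model_config, seed=int(rng.integers(2**31)))
    latents = LatentTable()
    for pid, _, _ in population:
        latents[pid] = rng.normal(0.0, latent_init_scale, size=model_config.latent_dim)
    if config.normalize:
        norm = NormStats.from_measurements([np.asarray(z) for _, z, _ in population])
    else:
        norm = NormStats(0.0, 1.0)
    coords_cache = {}
    opt_theta = Adam({k: v.shape for k, v in model.theta.items()})
    opt_lat = {
        pid: Adam({"e": (model_config.latent_dim,)}) for pid, _, _ in population
    }
    n = len(population)
    losses = np.empty(config.total_steps)
    for step in range(config.total_steps):
        pid, z, operator = population[step % n]
        key = operator.grid_size
        if key not in coords_cache:
            coords_cache[key] = pixel_centers((key,) * model_config.in_dim)
        lr = lr_schedule(step + 1, config)
        loss, grads, grad_latent, _ = _loss_and_grads(
            model, latents[pid], operator, z, norm, coords_cache[key]
        )
        losses[step] = loss
        opt_theta.step(model.theta, grads, lr)
        e = {"e": latents[pid]}
        opt_lat[pid].step(e, {"e": grad_latent}, lr)
        latents[pid] = e["e"]
    return Checkpoint(
        model=model,
        latents=latents,
        norm_stats=norm,
        train_patient_ids=tuple(pid for pid, _, _ in population),
        loss_history=losses,
    )


def reconstruct(
    checkpoint: Checkpoint | None,
    measurement,
    operator,
    config: TrainConfig,
    ground_truth: ImageGrid | None = None,
    optimize_latent: bool = False,
):
    """Fit the coordinate network to one patient's measurement.

    With a checkpoint, theta starts from the pretrained weights and the latent
    is drawn randomly (seeded) and frozen; without one (the no-prior
    ablation), theta is freshly initialized and the latent is zero.  Returns
    (rendered ImageGrid, FitTrace); trace entry t is the state after t steps,
    so the trace has total_steps + 1 entries.
    """
    rng = np.random.default_rng(config.seed)
    if checkpoint is not None:
        model = checkpoint.model.copy()
        mc = model.config
        latent = rng.normal(0.0, 0.01, size=mc.latent_dim)
        norm = checkpoint.norm_stats if config.normalize else NormStats(0.0, 1.0)
    else:
        mc = ModelConfig()
        model = init_model(mc, seed=int(rng.integers(2**31)))
        latent = np.zeros(mc.latent_dim)
        norm = (
            NormStats.from_measurements([np.asarray(measurement)])
            if config.normalize
            else NormStats(0.0, 1.0)
        )
    return _fit(model, latent, measurement, operator, config, norm,
                ground_truth, optimize_latent)


def reconstruct_from_scratch(
    model_config: ModelConfig,
    measurement,
    operator,
    config: TrainConfig,
    ground_truth: ImageGrid | None = None,
):
    """No-prior reconstruction with an explicit (e.g. desk-scale) architecture."""
    rng = np.random.default_rng(config.seed)
    model = init_model(model_config, seed=int(rng.integers(2**31)))
    latent = np.zeros(model_config.latent_dim)
    norm = (
        NormStats.from_measurements([np.asarray(measurement)])
        if config.normalize
        else NormStats(0.0, 1.0)
    )
    return _fit(model, latent, measurement, operator, config, norm, ground_truth, False)


def _fit(model, latent, measurement, operator, config, norm, ground_truth, optimize_latent):
    z = np.asarray(measurement).ravel()
    if z.size != operator.n_measurements:
        raise ValueError("measurement length does not match operator geometry")
    coords = pixel_centers((operator.grid_size,) * model.config.in_dim)
    gt = ground_truth.values.ravel() if ground_truth is not None else None
    opt_theta = Adam({k: v.shape for k, v in model.theta.items()})
    opt_lat = Adam({"e": latent.shape}) if optimize_latent else None
    resids, mses = [], []

    def record(loss, flat):
        resids.append(loss)
        if gt is not None:
            mses.append(float(np.mean((flat - gt) ** 2)))

    loss, grads, grad_latent, flat = _loss_and_grads(
        model, latent, operator, z, norm, coords
    )
    record(loss, flat)
    for step in range(config.total_steps):
        lr = lr_schedule(step + 1, config)
        opt_theta.step(model.theta, grads, lr)
        if optimize_latent:
            e = {"e": latent}
            opt_lat.step(e, {"e": grad_latent}, lr)
            latent = e["e"]
        loss, grads, grad_latent, flat = _loss_and_grads(
            model, latent, operator, z, norm, coords
        )
        record(loss, flat)
    size = operator.grid_size
    image = ImageGrid(flat.reshape((size,) * model.config.in_dim))
    trace = FitTrace(
        meas_residual=np.array(resids),
        image_mse=np.array(mses) if gt is not None else None,
    )
    return image, trace


def ablation_experiment(
    n_train_patients: int,
    n_views: int = 10,
    seed: int = 0,
    size: int = 64,
    pretrain_steps: int = 2000,
    recon_steps: int = 300,
    model_config: ModelConfig | None = None,
    phantom_config=None,
    checkpoint: Checkpoint | None = None,
    held_out_index: int | None = None,
):
    """Paired with/without-prior reconstruction of one held-out patient.

    Pretrains on patients 0..n_train_patients-1 (unless a checkpoint is
    supplied) and reconstructs the held-out patient (index n_train_patients by
    default) from its sparse sinogram twice: once finetuning from the shared
    checkpoint, once from scratch.  Returns a dict with the paired traces,
    renders and ground truth."""
    from .operators import RadonOperator, sparse_view_geometry
    from .phantoms import rasterize, sample_random_phantom

    model_config = model_config or ModelConfig()
    geom = sparse_view_geometry(n_views, size)
    operator = RadonOperator(geom, size)
    if checkpoint is None:
        population = []
        for i in range(n_train_patients):
            ph = sample_random_phantom(seed, i, phantom_config)
            img = rasterize(ph, size)
            population.append((ph.patient_id, operator.measure(img).values, operator))
        checkpoint = pretrain(
            population,
            TrainConfig(total_steps=pretrain_steps, seed=seed),
            model_config,
        )
    idx = n_train_patients if held_out_index is None else held_out_index
    held = sample_random_phantom(seed, idx, phantom_config)
    if held.patient_id in checkpoint.train_patient_ids:
        raise ValueError("held-out patient appears in the pretraining set")
    truth = rasterize(held, size)
    z = operator.measure(truth).values
    rc = TrainConfig(total_steps=recon_steps, seed=seed + 1 + idx)
    img_prior, trace_prior = reconstruct(checkpoint, z, operator, rc, ground_truth=truth)
    img_no, trace_no = reconstruct_from_scratch(
        model_config, z, operator, rc, ground_truth=truth
    )
    return {
        "checkpoint": checkpoint,
        "truth": truth,
        "with_prior": (img_prior, trace_prior),
        "without_prior": (img_no, trace_no),
        "operator": operator,
        "measurement": z,
    }
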