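"""Latent-conditioned sinusoidal residual MLP (the coordinate network).

The network maps a continuous coordinate x in [-1, 1]^d to an image value:

    h0   = sin(omega * (x W_in + b_in))
    c    = sin(omega * (sin(omega * (e Wc1 + bc1)) Wc2 + bc2))   # conditioning
    h_k+1 = h_k + sin(omega * (h_k W_k + b_k)) + c               # residual block
    f(x) = h_L W_out + b_out

Every patient i owns a low-dimensional latent e_i (default length 16); the
shared weights theta are common to the whole population.  The conditioning MLP
(two affine layers of hidden_width neurons, sine activations) turns the latent
into a single feature vector that is added to every block's output, so the
same network renders different patients.

Sine activations follow the SIREN initialization: the first layer is drawn
uniform in +-1/in_dim, later layers uniform in +-sqrt(6/width)/omega, keeping
pre-activations well-scaled at any depth.  Everything here is plain numpy with
analytic reverse-mode gradients (`backward`) with respect to the shared
weights, the latent, and the coordinates; `model.gradients` is validated
against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelConfig", "INRModel", "LatentTable", "init_model", "condition", "render"]


@dataclass(frozen=True)
class ModelConfig:
    n_blocks: int = 6
    hidden_width: int = 256
    latent_dim: int = 16
    cond_layers: int = 2
    out_dim: int = 1
    sine_omega: float = 30.0
    in_dim: int = 2

    def __post_init__(self):
        for name in ("n_blocks", "hidden_width", "latent_dim", "cond_layers", "out_dim", "in_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.sine_omega <= 0:
            raise ValueError("sine_omega must be positive")
        if self.in_dim not in (2, 3):
            raise ValueError("in_dim must be 2 or 3")
        if self.cond_layers != 2:
            raise ValueError("conditioning MLP is fixed at 2 affine layers")

    def to_jsonable(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "hidden_width": self.hidden_width,
            "latent_dim": self.latent_dim,
            "cond_layers": self.cond_layers,
            "out_dim": self.out_dim,
            "sine_omega": self.sine_omega,
            "in_dim": self.in_dim,
        }


class LatentTable(dict):
    """patient_id -> latent vector; all entries share one length."""

    def __setitem__(self, key, value):
        vec = np.asarray(value, dtype=float)
        if vec.ndim != 1:
            raise ValueError("latent must be a vector")
        if not np.all(np.isfinite(vec)):
            raise ValueError("latent must be finite")
        if self:
            (first,) = {v.shape for v in self.values()} | {vec.shape}
            if vec.shape != first:
                raise ValueError("all latents must share one length")
        super().__setitem__(key, vec)


def init_model(config: ModelConfig, seed: int) -> "INRModel":
    """SIREN-style initialization, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    w = config.hidden_width
    om = config.sine_omega
    hid = np.sqrt(6.0 / w) / om

    def u(shape, bound):
        return rng.uniform(-bound, bound, size=shape)

    params = {
        "W_in": u((config.in_dim, w), 1.0 / config.in_dim),
        "b_in": np.zeros(w),
        "Wc1": u((config.latent_dim, w), np.sqrt(6.0 / config.latent_dim) / om),
        "bc1": np.zeros(w),
        "Wc2": u((w, w), hid),
        "bc2": np.zeros(w),
        "W_out": u((w, config.out_dim), hid),
        "b_out": np.zeros(config.out_dim),
    }
    for k in range(config.n_blocks):
        params[f"W_{k}"] = u((w, w), hid)
        params[f"b_{k}"] = np.zeros(w)
    return INRModel(params, config)


@dataclass
class INRModel:
    """Shared weights theta plus architecture config.

    Parameters live in a flat dict of numpy arrays; `n_parameters` is a pure
    function of the config.
    """

    theta: dict
    config: ModelConfig

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.theta.values()))

    def copy(self) -> "INRModel":
        return INRModel({k: v.copy() for k, v in self.theta.items()}, self.config)

    # ---- forward ---------------------------------------------------------

    def _condition_cache(self, latent: np.ndarray):
        p, om = self.theta, self.config.sine_omega
        latent = np.asarray(latent, dtype=float)
        if latent.shape != (self.config.latent_dim,):
            raise ValueError(
                f"latent length {latent.shape} != latent_dim {self.config.latent_dim}"
            )
        u1 = om * (latent @ p["Wc1"] + p["bc1"])
        a1 = np.sin(u1)
        u2 = om * (a1 @ p["Wc2"] + p["bc2"])
        c = np.sin(u2)
        return c, (latent, u1, a1, u2)

    def forward(self, latent: np.ndarray, coords: np.ndarray, cache: bool = False):
        """Evaluate f_{theta,e}(coords); coords has shape (batch, in_dim)."""
        p, om = self.theta, self.config.sine_omega
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.shape[1] != self.config.in_dim:
            raise ValueError("coordinate dimensionality mismatch")
        c, cond_cache = self._condition_cache(latent)
        u0 = om * (coords @ p["W_in"] + p["b_in"])
        h = np.sin(u0)
        us, hs = [], []
        for k in range(self.config.n_blocks):
            hs.append(h)
            u = om * (h @ p[f"W_{k}"] + p[f"b_{k}"])
            us.append(u)
            h = h + np.sin(u) + c
        out = h @ p["W_out"] + p["b_out"]
        if cache:
            return out, (coords, u0, us, hs, h, c, cond_cache)
        return out

    # ---- reverse mode ----------------------------------------------------

    def backward(self, cache, grad_out: np.ndarray):
        """Gradients of sum(grad_out * output) w.r.t. theta, latent, coords.

        Returns (grad_theta: dict, grad_latent, grad_coords)."""
        p, om = self.theta, self.config.sine_omega
        coords, u0, us, hs, h_last, c, (latent, u1, a1, u2) = cache
        g = np.atleast_2d(np.asarray(grad_out, dtype=float))
        grads = {}
        grads["W_out"] = h_last.T @ g
        grads["b_out"] = g.sum(axis=0)
        dh = g @ p["W_out"].T
        dc_total = np.zeros_like(c)
        for k in reversed(range(self.config.n_blocks)):
            dc_total += dh.sum(axis=0)
            du = dh * np.cos(us[k]) * om
            grads[f"W_{k}"] = hs[k].T @ du
            grads[f"b_{k}"] = du.sum(axis=0)
            dh = dh + du @ p[f"W_{k}"].T
        du0 = dh * np.cos(u0) * om
        grads["W_in"] = coords.T @ du0
        grads["b_in"] = du0.sum(axis=0)
        grad_coords = du0 @ p["W_in"].T
        # conditioning branch
        du2 = dc_total * np.cos(u2) * om
        grads["Wc2"] = np.outer(a1, du2)
        grads["bc2"] = du2
        da1 = du2 @ p["Wc2"].T
        du1 = da1 * np.cos(u1) * om
        grads["Wc1"] = np.outer(latent, du1)
        grads["bc1"] = du1
        grad_latent = du1 @ p["Wc1"].T
        return grads, grad_latent, grad_coords

    def gradients(self, latent, coords, grad_out):
        """One-call forward + backward (used by tests and the optimizer)."""
        _, cache = self.forward(latent, coords, cache=True)
        return self.backward(cache, grad_out)


def condition(latent: np.ndarray, model: INRModel) -> np.ndarray:
    """Feature vector (length hidden_width) added to every block's output."""
    c, _ = model._condition_cache(latent)
    return c


def render(model: INRModel, latent: np.ndarray, grid_size: int, chunk: int = 16384):
    """Evaluate the network on every pixel center of a grid_size^in_dim grid.

    The representation is continuous, so any grid_size works; rendering twice
    is bit-identical.  Returns an ImageGrid.
    """
    from .phantoms import ImageGrid, pixel_centers

    shape = (grid_size,) * model.config.in_dim
    pts = pixel_centers(shape)
    out = np.empty(pts.shape[0])
    for start in range(0, pts.shape[0], chunk):
        out[start : start + chunk] = model.forward(
            latent, pts[start : start + chunk]
        )[:, 0]
    return ImageGrid(out.reshape(shape))
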