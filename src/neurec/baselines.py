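"""Classical reconstruction baselines: filtered back-projection and SART.

FBP filters each projection row with the ramp filter (built from the
Ram-Lak real-space kernel, so the DC sample is handled correctly) windowed by
a Hann raised cosine, then backprojects with the package's Radon adjoint and
scales by pi / (2 * n_angles) times the geometry factor detector_spacing /
pixel_area that converts the bilinear-weight adjoint into the continuous
backprojection integral.  The Hann window removes the highest frequencies,
trading resolution for noise/streak suppression.

SART performs the simultaneous update

    x <- x + relaxation * V^-1 F^T W^-1 (z - F x)

with V, W the diagonal column/row sums of the ray matrix (zero sums masked),
processing all angles in every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import CTGeometry, Sinogram, system_matrix
from .phantoms import ImageGrid

__all__ = ["FBPConfig", "SARTConfig", "fbp", "sart"]


@dataclass(frozen=True)
class FBPConfig:
    filter_name: str = "hann"

    def __post_init__(self):
        if self.filter_name not in ("ramp", "hann"):
            raise ValueError(f"unknown filter {self.filter_name!r}")


@dataclass(frozen=True)
class SARTConfig:
    n_iterations: int = 50
    relaxation: float = 1.0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not (0.0 < self.relaxation < 2.0):
            raise ValueError("relaxation must lie in (0, 2)")


def _ramp_kernel(n: int) -> np.ndarray:
    """Frequency response of the band-limited ramp (Ram-Lak), length n.

    Built as the DFT of the real-space filter kernel h[0] = 1/4,
    h[k] = -1/(pi*k)^2 for odd k, 0 for even k, which avoids the DC-bias
    artifact of sampling |f| directly."""
    k = np.concatenate([np.arange(1, n // 2 + 1, 2), np.arange(n // 2 - 1, 0, -2)])
    h = np.zeros(n)
    h[0] = 0.25
    h[1::2] = -1.0 / (np.pi * k) ** 2
    return 2.0 * np.real(np.fft.fft(h))


def fbp(sino: Sinogram, size: int, config: FBPConfig = FBPConfig()) -> ImageGrid:
    """Filtered back-projection of a parallel-beam sinogram onto size^2."""
    geom = sino.geometry
    n_det = geom.n_detectors
    pad = max(64, int(2 ** np.ceil(np.log2(2 * n_det))))
    filt = _ramp_kernel(pad)
    if config.filter_name == "hann":
        freq = np.fft.fftfreq(pad)
        window = 0.5 * (1.0 + np.cos(2.0 * np.pi * freq))  # raised cosine on the ramp support
        filt = filt * window
    padded = np.zeros((geom.n_angles, pad))
    padded[:, :n_det] = sino.values
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * filt, axis=1))[:, :n_det]
    back = system_matrix(geom, size).T @ filtered.ravel()
    pixel_area = (2.0 / size) ** 2
    scale = (np.pi / (2.0 * geom.n_angles)) * geom.detector_spacing / pixel_area
    # the discrete filter operates on samples, not on the physical axis:
    # dividing by the detector spacing converts the convolution sum to the
    # physical filtering integral
    scale /= geom.detector_spacing
    return ImageGrid((back * scale).reshape(size, size))


def sart(
    sino: Sinogram,
    size: int,
    config: SARTConfig = SARTConfig(),
    init: ImageGrid | None = None,
    return_residuals: bool = False,
):
    """Simultaneous algebraic reconstruction from a sinogram.

    Returns the reconstructed ImageGrid; with ``return_residuals`` also the
    per-iteration row-weighted measurement residual norms (nonincreasing for
    relaxation = 1)."""
    W = system_matrix(sino.geometry, size)
    z = sino.values.ravel()
    row_sum = np.asarray(W.sum(axis=1)).ravel()
    col_sum = np.asarray(W.sum(axis=0)).ravel()
    row_ok = row_sum > 1e-12
    col_ok = col_sum > 1e-12
    inv_row = np.where(row_ok, 1.0 / np.where(row_ok, row_sum, 1.0), 0.0)
    inv_col = np.where(col_ok, 1.0 / np.where(col_ok, col_sum, 1.0), 0.0)
    x = np.zeros(W.shape[1]) if init is None else init.values.ravel().copy()
    residuals = []
    for _ in range(config.n_iterations):
        r = z - W @ x
        residuals.append(float(np.sqrt(np.sum(inv_row * r * r))))
        x = x + config.relaxation * inv_col * (W.T @ (inv_row * r))
    r = z - W @ x
    residuals.append(float(np.sqrt(np.sum(inv_row * r * r))))
    img = ImageGrid(x.reshape(size, size))
    if return_residuals:
        return img, np.array(residuals)
    return img
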