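"""Full-reference image quality metrics: MSE, PSNR, SSIM.

MSE and PSNR are the usual closed forms; SSIM is the standard windowed index
(Gaussian window sigma = 1.5, 11x11 support, K1 = 0.01, K2 = 0.03, averaged
over windows) computed by scikit-image.  ``data_range`` defaults to the
max - min of the reference (ground-truth) image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .phantoms import ImageGrid

__all__ = ["MetricReport", "mse", "psnr", "ssim", "evaluate"]


def _values(img):
    return img.values if isinstance(img, ImageGrid) else np.asarray(img, float)


def _check_shapes(a, b):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(a, b) -> float:
    a, b = _values(a), _values(b)
    _check_shapes(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, data_range: float) -> float:
    """10 * log10(data_range^2 / MSE); +inf for identical images."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    err = mse(a, b)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / err))


def ssim(a, b, data_range: float) -> float:
    a, b = _values(a), _values(b)
    _check_shapes(a, b)
    if min(a.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


@dataclass(frozen=True)
class MetricReport:
    mse: float
    psnr_db: float
    ssim: float
    data_range: float

    def to_jsonable(self) -> dict:
        return {
            "mse": self.mse,
            "psnr_db": self.psnr_db,
            "ssim": self.ssim,
            "data_range": self.data_range,
        }


def evaluate(pred, truth, data_range: float | None = None) -> MetricReport:
    """All three metrics of a reconstruction against the ground truth."""
    t = _values(truth)
    if data_range is None:
        data_range = float(t.max() - t.min())
        if data_range == 0.0:
            data_range = 1.0
    return MetricReport(
        mse=mse(pred, truth),
        psnr_db=psnr(pred, truth, data_range),
        ssim=ssim(pred, truth, data_range),
        data_range=data_range,
    )
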