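"""Linearized measurement operators for sparse-view CT and undersampled MRI.

Both modalities are modelled as a linear map z = F y from the image (flattened
pixel values on the [-1, 1]^2 grid) to the measurement vector.  The CT
operator is a discrete parallel-beam Radon transform: each (angle, detector)
pair defines a ray, sampled every half pixel with bilinear interpolation, and
the line integral is the step-weighted sum of the samples.  Because the
operator is materialized as a sparse matrix of those bilinear weights, the
adjoint (unfiltered backprojection) is exactly the transpose — the pair passes
the inner-product identity <Fx, y> = <x, F^T y> to machine precision, which is
what gradient-based fitting and SART require.

The MRI operator is the unnormalized 2D DFT restricted to a Cartesian k-space
mask; its adjoint is the zero-filled inverse transform scaled by the pixel
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .phantoms import ImageGrid

__all__ = [
    "CTGeometry",
    "Sinogram",
    "KSpaceMask",
    "KSpaceSet",
    "sparse_view_geometry",
    "radon_apply",
    "radon_adjoint",
    "operator_matrix",
    "system_matrix",
    "fourier_apply",
    "fourier_adjoint",
]

_DIAG = np.sqrt(2.0)  # half-diagonal of the [-1,1]^2 box


@dataclass(frozen=True)
class CTGeometry:
    """Parallel-beam geometry: projection angles and a detector array whose
    bins span the grid diagonal [-sqrt(2), sqrt(2)] in normalized units."""

    angles_deg: tuple
    n_detectors: int

    def __post_init__(self):
        angles = tuple(float(a) for a in self.angles_deg)
        object.__setattr__(self, "angles_deg", angles)
        if len(angles) == 0:
            raise ValueError("need at least one angle")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("angles must be strictly increasing")
        if not all(0.0 <= a < 180.0 for a in angles):
            raise ValueError("angles must lie in [0, 180)")
        if self.n_detectors < 1:
            raise ValueError("n_detectors must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def detector_spacing(self) -> float:
        return 2.0 * _DIAG / self.n_detectors

    def detector_offsets(self) -> np.ndarray:
        """Signed perpendicular offsets of the detector-bin centers."""
        return -_DIAG + (np.arange(self.n_detectors) + 0.5) * self.detector_spacing


def sparse_view_geometry(n_views: int, size: int) -> CTGeometry:
    """Default geometry: n_views angles uniform over [0, 180) and enough
    detector bins for ~pixel-sized spacing along the diagonal."""
    angles = tuple(np.arange(n_views) * (180.0 / n_views))
    n_det = int(np.ceil(_DIAG * size)) + 1
    return CTGeometry(angles, n_det)


@dataclass
class Sinogram:
    values: np.ndarray
    geometry: CTGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expect = (self.geometry.n_angles, self.geometry.n_detectors)
        if self.values.shape != expect:
            raise ValueError(f"sinogram shape {self.values.shape} != geometry {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")


_matrix_cache: dict = {}


def system_matrix(geom: CTGeometry, size: int) -> sp.csr_matrix:
    """Sparse (M x N) ray-weight matrix; cached per (geometry, size).

    Rays are sampled every half pixel (step h = 1/size in normalized units)
    over the full diagonal; each sample deposits bilinear weights times h on
    its four neighbouring pixels.  Samples falling outside the grid contribute
    nothing (the phantom support is inside the box by construction).
    """
    key = (geom.angles_deg, geom.n_detectors, size)
    if key in _matrix_cache:
        return _matrix_cache[key]
    h = 1.0 / size  # half-pixel step along the ray
    n_steps = int(np.ceil(2.0 * _DIAG / h)) + 1
    t = -_DIAG + np.arange(n_steps) * h
    s = geom.detector_offsets()
    n_det = geom.n_detectors
    N = size * size
    blocks = []
    for ang in geom.angles_deg:
        th = np.deg2rad(ang)
        nvec = np.array([np.cos(th), np.sin(th)])  # detector direction
        dvec = np.array([-np.sin(th), np.cos(th)])  # ray direction
        # sample coordinates for every (detector, step)
        x = s[:, None] * nvec[0] + t[None, :] * dvec[0]
        y = s[:, None] * nvec[1] + t[None, :] * dvec[1]
        # fractional pixel indices (pixel centers at -1 + (i+0.5)*2/size)
        fx = (x + 1.0) * (size / 2.0) - 0.5
        fy = (y + 1.0) * (size / 2.0) - 0.5
        ix = np.floor(fx).astype(np.int64)
        iy = np.floor(fy).astype(np.int64)
        wx = fx - ix
        wy = fy - iy
        rows = np.broadcast_to(np.arange(n_det)[:, None], fx.shape)
        data_list, row_list, col_list = [], [], []
        for dx, dy, w in (
            (0, 0, (1 - wx) * (1 - wy)),
            (1, 0, wx * (1 - wy)),
            (0, 1, (1 - wx) * wy),
            (1, 1, wx * wy),
        ):
            px = ix + dx
            py = iy + dy
            ok = (px >= 0) & (px < size) & (py >= 0) & (py < size) & (w > 0)
            col_list.append((py[ok] * size + px[ok]))
            row_list.append(rows[ok])
            data_list.append(w[ok] * h)
        block = sp.coo_matrix(
            (np.concatenate(data_list), (np.concatenate(row_list), np.concatenate(col_list))),
            shape=(n_det, N),
        ).tocsr()
        blocks.append(block)
    mat = sp.vstack(blocks, format="csr")
    if len(_matrix_cache) > 8:
        _matrix_cache.clear()
    _matrix_cache[key] = mat
    return mat


def radon_apply(image: ImageGrid | np.ndarray, geom: CTGeometry) -> Sinogram:
    """Parallel-beam line integrals of a square image."""
    vals = image.values if isinstance(image, ImageGrid) else np.asarray(image, float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("radon_apply requires a square 2D image")
    size = vals.shape[0]
    W = system_matrix(geom, size)
    sino = (W @ vals.ravel()).reshape(geom.n_angles, geom.n_detectors)
    return Sinogram(sino, geom)


def radon_adjoint(sino: Sinogram, size: int) -> ImageGrid:
    """Unfiltered backprojection F^T z onto a size x size grid."""
    W = system_matrix(sino.geometry, size)
    img = (W.T @ sino.values.ravel()).reshape(size, size)
    return ImageGrid(img)


def operator_matrix(geom: CTGeometry, size: int) -> np.ndarray:
    """Dense (M x N) matrix whose action equals radon_apply on every basis
    image.  Restricted to small grids: intended as an oracle for tests,
    rank/null-space arguments and the dense-matrix loss check."""
    if size > 32:
        raise ValueError("operator_matrix is capped at size <= 32")
    M = geom.n_angles * geom.n_detectors
    N = size * size
    cols = np.zeros((M, N))
    basis = np.zeros((size, size))
    for j in range(N):
        basis.flat[j] = 1.0
        cols[:, j] = radon_apply(basis, geom).values.ravel()
        basis.flat[j] = 0.0
    return cols


@dataclass
class KSpaceMask:
    """Boolean Cartesian frequency mask (True = sampled), numpy fft layout."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError("mask must sample at least one frequency")

    @property
    def sampled_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class KSpaceSet:
    values: np.ndarray
    mask: KSpaceMask

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (int(self.mask.mask.sum()),):
            raise ValueError("k-space value count must equal mask popcount")


def fourier_apply(image: ImageGrid | np.ndarray, mask: KSpaceMask) -> KSpaceSet:
    """Unnormalized 2D DFT of the image restricted to the masked frequencies."""
    vals = image.values if isinstance(image, ImageGrid) else np.asarray(image, float)
    if vals.shape != mask.mask.shape:
        raise ValueError("mask grid must match image grid")
    spectrum = np.fft.fft2(vals)
    return KSpaceSet(spectrum[mask.mask], mask)


class RadonOperator:
    """F as a flat linear map: apply/adjoint on flattened images.

    This is the object the fitting loop consumes; it shares the exact sparse
    matrix used by radon_apply, so its adjoint is the true transpose."""

    def __init__(self, geom: CTGeometry, size: int):
        self.geometry = geom
        self.grid_size = size
        self._W = system_matrix(geom, size)

    @property
    def n_measurements(self) -> int:
        return self._W.shape[0]

    def apply_flat(self, flat: np.ndarray) -> np.ndarray:
        return self._W @ flat

    def adjoint_flat(self, vec: np.ndarray) -> np.ndarray:
        return self._W.T @ np.real(vec)

    def measure(self, image: ImageGrid) -> Sinogram:
        return radon_apply(image, self.geometry)


class FourierOperator:
    """Masked unnormalized DFT as a flat linear map (complex measurements)."""

    def __init__(self, mask: KSpaceMask):
        self.mask = mask
        self.grid_size = mask.mask.shape[0]
        if mask.mask.shape[0] != mask.mask.shape[1]:
            raise ValueError("square grids only")

    @property
    def n_measurements(self) -> int:
        return int(self.mask.mask.sum())

    def apply_flat(self, flat: np.ndarray) -> np.ndarray:
        img = np.asarray(flat, float).reshape(self.mask.mask.shape)
        return np.fft.fft2(img)[self.mask.mask]

    def adjoint_flat(self, vec: np.ndarray) -> np.ndarray:
        full = np.zeros(self.mask.mask.shape, dtype=complex)
        full[self.mask.mask] = vec
        return np.real(np.fft.ifft2(full)).ravel() * full.size

    def measure(self, image: ImageGrid) -> KSpaceSet:
        return fourier_apply(image, self.mask)


def fourier_adjoint(kspace: KSpaceSet) -> ImageGrid:
    """Adjoint of fourier_apply: zero-filled conjugate transform.

    With the unnormalized forward DFT, the adjoint is n_pixels * ifft2 of the
    zero-filled spectrum (real part, since the image space is real)."""
    full = np.zeros(kspace.mask.mask.shape, dtype=complex)
    full[kspace.mask.mask] = kspace.values
    img = np.fft.ifft2(full) * full.size
    return ImageGrid(np.real(img))
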