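"""Parametric ellipse phantoms: the canonical Shepp-Logan head and randomized
populations of Shepp-Logan-like "patients".

A phantom is an ordered list of ellipses (2D) or ellipsoids (3D) living in the
normalized box [-1, 1]^d.  Rasterization sums the additive intensity of every
ellipse containing a pixel center — a hard point-in-ellipse test with no
anti-aliasing, so the rasterizer is exactly linear in the ellipse list and
matches a brute-force per-pixel oracle bit for bit.  The randomized population
plays the role of a patient cohort: every phantom shares a skull-like outer
shell (the "common anatomy") while interior ellipses vary per patient.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ellipse",
    "EllipsePhantom",
    "ImageGrid",
    "PhantomConfig",
    "canonical_shepp_logan",
    "sample_random_phantom",
    "rasterize",
    "generate_population",
    "pixel_centers",
]


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse/ellipsoid.

    center and semi_axes are in normalized coordinates ([-1, 1]^d box);
    rotation_deg is the in-plane angle for 2D, or (phi, theta, psi) Euler
    angles (z-x-z convention, degrees) for 3D; intensity is added to every
    pixel whose center lies inside.
    """

    center: tuple
    semi_axes: tuple
    rotation_deg: tuple
    intensity: float

    def __post_init__(self):
        if len(self.center) != len(self.semi_axes):
            raise ValueError("center and semi_axes dimensionality mismatch")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be strictly positive")

    @property
    def dim(self) -> int:
        return len(self.center)

    def rotation_matrix(self) -> np.ndarray:
        if self.dim == 2:
            (ang,) = self.rotation_deg
            c, s = np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))
            return np.array([[c, -s], [s, c]])
        phi, theta, psi = (np.deg2rad(a) for a in self.rotation_deg)

        def rz(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

        def rx(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])

        return rz(phi) @ rx(theta) @ rz(psi)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of the (n, d) points inside the ellipse (boundary in)."""
        rel = points - np.asarray(self.center)
        local = rel @ self.rotation_matrix()  # R^T applied to each row
        scaled = local / np.asarray(self.semi_axes)
        return (scaled**2).sum(axis=-1) <= 1.0


@dataclass(frozen=True)
class EllipsePhantom:
    """Ordered ellipse set describing one patient."""

    ellipses: tuple
    patient_id: str

    def __post_init__(self):
        if len(self.ellipses) == 0:
            raise ValueError("phantom must contain at least one ellipse")

    @property
    def dim(self) -> int:
        return self.ellipses[0].dim

    def to_jsonable(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "ellipses": [dataclasses.asdict(e) for e in self.ellipses],
        }


@dataclass
class ImageGrid:
    """Pixel/voxel lattice over the physical box [-1, 1]^d.

    Pixel-center convention: index (0, ..., 0) maps to the corner-most pixel
    center, i.e. coordinate -1 + spacing/2 along every axis.  ``values`` has
    shape (H, W) for 2D (row = y, col = x) or (D, H, W) for 3D.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("ImageGrid must be 2D or 3D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageGrid values must be finite")

    @property
    def dim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def spacing(self) -> tuple:
        return tuple(2.0 / n for n in self.values.shape)


def pixel_centers(shape) -> np.ndarray:
    """Coordinates of all pixel centers, shape (prod(shape), d).

    Axis order of the returned coordinate columns matches Cartesian (x, y[, z])
    while the array index order is (row=y, col=x) in 2D and (z, y, x) in 3D, so
    rasters display with x increasing along columns.
    """
    axes = [(-1.0 + (np.arange(n) + 0.5) * (2.0 / n)) for n in shape]
    if len(shape) == 2:
        yy, xx = np.meshgrid(axes[0], axes[1], indexing="ij")
        return np.stack([xx.ravel(), yy.ravel()], axis=1)
    zz, yy, xx = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def rasterize(phantom: EllipsePhantom, size: int) -> ImageGrid:
    """Sum of ellipse intensities at pixel centers on a size^d grid."""
    if size < 8:
        raise ValueError("size must be >= 8")
    shape = (size,) * phantom.dim
    pts = pixel_centers(shape)
    vals = np.zeros(pts.shape[0])
    for e in phantom.ellipses:
        vals[e.contains(pts)] += e.intensity
    return ImageGrid(vals.reshape(shape))


# Modified (Toft / Kak-Slaney) Shepp-Logan table: (intensity, a, b, x0, y0, angle)
# with the visibility-rescaled intensities conventional in CT software, so the
# rasterized values lie in [0, 1] with the skull at 1.0.
_SHEPP_LOGAN_2D = [
    (1.00, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.80, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.10, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.10, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.10, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.10, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.605, 0.0),
]

# 3D table (Kak-Slaney ellipsoids, modified intensities):
# (intensity, a, b, c, x0, y0, z0, phi)
_SHEPP_LOGAN_3D = [
    (1.00, 0.69, 0.92, 0.81, 0.0, 0.0, 0.0, 0.0),
    (-0.80, 0.6624, 0.8740, 0.780, 0.0, -0.0184, 0.0, 0.0),
    (-0.20, 0.1100, 0.3100, 0.220, 0.22, 0.0, 0.0, -18.0),
    (-0.20, 0.1600, 0.4100, 0.280, -0.22, 0.0, 0.0, 18.0),
    (0.10, 0.2100, 0.2500, 0.410, 0.0, 0.35, -0.15, 0.0),
    (0.10, 0.0460, 0.0460, 0.050, 0.0, 0.1, 0.25, 0.0),
    (0.10, 0.0460, 0.0460, 0.050, 0.0, -0.1, 0.25, 0.0),
    (0.10, 0.0460, 0.0230, 0.050, -0.08, -0.605, 0.0, 0.0),
    (0.10, 0.0230, 0.0230, 0.020, 0.0, -0.606, 0.0, 0.0),
    (0.10, 0.0230, 0.0460, 0.020, 0.06, -0.605, 0.0, 0.0),
]


def canonical_phantom(dim: int = 2) -> EllipsePhantom:
    """The standard Shepp-Logan head as an ellipse set (before rasterization)."""
    if dim == 2:
        ells = tuple(
            Ellipse((x0, y0), (a, b), (ang,), inten)
            for inten, a, b, x0, y0, ang in _SHEPP_LOGAN_2D
        )
    elif dim == 3:
        ells = tuple(
            Ellipse((x0, y0, z0), (a, b, c), (phi, 0.0, 0.0), inten)
            for inten, a, b, c, x0, y0, z0, phi in _SHEPP_LOGAN_3D
        )
    else:
        raise ValueError("dim must be 2 or 3")
    return EllipsePhantom(ells, patient_id="shepp-logan")


def canonical_shepp_logan(size: int, dim: int = 2) -> ImageGrid:
    """Rasterize the standard Shepp-Logan head phantom on a size^dim grid."""
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    if size < 8:
        raise ValueError("size must be >= 8")
    return rasterize(canonical_phantom(dim), size)


@dataclass(frozen=True)
class PhantomConfig:
    """Ranges for the randomized patient generator (all draws i.i.d. uniform).

    ``include_skull`` adds a jittered two-ellipse shell (bright rim over a
    moderate interior) shared by every patient, emulating the common anatomy
    the interpatient prior is supposed to capture.  Interior ellipse count,
    axes, rotations and intensities are drawn uniformly within the ranges.
    """

    dim: int = 2
    n_ellipses: tuple = (3, 7)  # inclusive range for interior ellipses
    axis_range: tuple = (0.05, 0.30)
    center_range: tuple = (-0.45, 0.45)
    intensity_range: tuple = (-0.15, 0.35)
    include_skull: bool = True
    skull_axis_range: tuple = (0.72, 0.92)
    support_margin: float = 0.95  # |center| + max axis must stay below this

    def validate(self):
        lo, hi = self.n_ellipses
        if lo > hi or hi < 1:
            raise ValueError("empty ellipse count range")
        if self.axis_range[0] > self.axis_range[1] or self.axis_range[0] <= 0:
            raise ValueError("invalid axis range")
        if self.intensity_range[0] > self.intensity_range[1]:
            raise ValueError("invalid intensity range")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")


def _rand_rotation(rng, dim):
    if dim == 2:
        return (float(rng.uniform(0.0, 180.0)),)
    return tuple(float(a) for a in rng.uniform(0.0, 180.0, size=3))


def sample_random_phantom(
    seed: int, patient_index: int, config: PhantomConfig | None = None
) -> EllipsePhantom:
    """Draw one randomized Shepp-Logan-style phantom.

    Reproducible: the output is a pure function of (seed, patient_index,
    config); each patient gets an independent random stream.
    """
    config = config or PhantomConfig()
    config.validate()
    rng = np.random.default_rng([abs(int(seed)), int(patient_index)])
    d = config.dim
    ells = []
    if config.include_skull:
        outer = np.sort(rng.uniform(*config.skull_axis_range, size=d))
        ells.append(Ellipse((0.0,) * d, tuple(outer), (0.0,) * (1 if d == 2 else 3), 1.0))
        ells.append(
            Ellipse((0.0,) * d, tuple(outer * 0.92), (0.0,) * (1 if d == 2 else 3), -0.8)
        )
    n = int(rng.integers(config.n_ellipses[0], config.n_ellipses[1] + 1))
    for _ in range(n):
        for _attempt in range(100):
            center = tuple(float(c) for c in rng.uniform(*config.center_range, size=d))
            axes = tuple(float(a) for a in rng.uniform(*config.axis_range, size=d))
            if float(np.linalg.norm(center)) + max(axes) <= config.support_margin:
                break
        rot = _rand_rotation(rng, d)
        inten = float(rng.uniform(*config.intensity_range))
        ells.append(Ellipse(center, axes, rot, inten))
    return EllipsePhantom(tuple(ells), patient_id=f"patient-{seed}-{patient_index}")


def generate_population(
    n_patients: int,
    seed: int,
    size: int,
    config: PhantomConfig | None = None,
    out_dir: str | pathlib.Path | None = None,
) -> list:
    """Generate a reproducible cohort of (patient_id, ImageGrid) pairs.

    When ``out_dir`` is given, writes one NIfTI (+ PNG for 2D) per patient and
    a JSON manifest mapping patient_id to file, seed and ellipse parameters.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    config = config or PhantomConfig()
    pairs = []
    phantoms = []
    for i in range(n_patients):
        ph = sample_random_phantom(seed, i, config)
        phantoms.append(ph)
        pairs.append((ph.patient_id, rasterize(ph, size)))
    if out_dir is not None:
        from . import io as nio

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": seed, "size": size, "patients": []}
        for ph, (pid, grid) in zip(phantoms, pairs):
            stem = out / pid
            nio.save_image(grid, stem)
            digest = hashlib.sha256(np.ascontiguousarray(grid.values).tobytes()).hexdigest()
            entry = ph.to_jsonable()
            entry["file"] = f"{pid}.nii.gz"
            entry["sha256"] = digest
            manifest["patients"].append(entry)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return pairs
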