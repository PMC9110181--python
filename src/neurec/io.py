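"""Disk formats: NIfTI/PNG images, .npy + JSON-sidecar measurements,
and the .npz training checkpoint with a versioned JSON header."""

from __future__ import annotations

import json
import pathlib

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .model import INRModel, LatentTable, ModelConfig
from .operators import CTGeometry, KSpaceMask, KSpaceSet, Sinogram
from .phantoms import ImageGrid
from .training import Checkpoint, NormStats

__all__ = [
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
    "save_kspace",
    "load_kspace",
    "save_checkpoint",
    "load_checkpoint",
]


def save_image(grid: ImageGrid, stem: str | pathlib.Path, png: bool = True) -> pathlib.Path:
    """Write a NIfTI volume (always) and, for 2D, an 8-bit PNG preview."""
    stem = pathlib.Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(grid.spacing) + [1.0] * (4 - grid.dim))
    nii_path = stem.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(grid.values.astype(np.float32), affine), nii_path)
    if png and grid.dim == 2:
        lo, hi = grid.values.min(), grid.values.max()
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        iio.imwrite(
            stem.with_suffix(".png"),
            ((grid.values - lo) * scale).astype(np.uint8),
        )
    return nii_path


def load_image(path: str | pathlib.Path) -> ImageGrid:
    return ImageGrid(np.asarray(nib.load(str(path)).dataobj, dtype=float))


def save_sinogram(sino: Sinogram, stem: str | pathlib.Path) -> pathlib.Path:
    stem = pathlib.Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), sino.values)
    sidecar = {
        "kind": "sinogram",
        "angles_deg": list(sino.geometry.angles_deg),
        "n_detectors": sino.geometry.n_detectors,
        "detector_spacing": sino.geometry.detector_spacing,
        "convention": "parallel-beam, offsets span the [-1,1]^2 diagonal",
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return stem.with_suffix(".npy")


def load_sinogram(stem: str | pathlib.Path) -> Sinogram:
    stem = pathlib.Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    geom = CTGeometry(tuple(meta["angles_deg"]), meta["n_detectors"])
    return Sinogram(np.load(stem.with_suffix(".npy")), geom)


def save_kspace(kspace: KSpaceSet, stem: str | pathlib.Path) -> pathlib.Path:
    stem = pathlib.Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), kspace.values)
    np.save(stem.parent / (stem.name + "_mask.npy"), kspace.mask.mask)
    sidecar = {
        "kind": "kspace",
        "grid_shape": list(kspace.mask.mask.shape),
        "sampled_fraction": kspace.mask.sampled_fraction,
        "convention": "unnormalized forward DFT, numpy fft frequency layout",
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return stem.with_suffix(".npy")


def load_kspace(stem: str | pathlib.Path) -> KSpaceSet:
    stem = pathlib.Path(stem)
    mask = KSpaceMask(np.load(stem.parent / (stem.name + "_mask.npy")))
    return KSpaceSet(np.load(stem.with_suffix(".npy")), mask)


def save_checkpoint(ckpt: Checkpoint, path: str | pathlib.Path) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "version": ckpt.version,
        "model_config": ckpt.model.config.to_jsonable(),
        "norm_stats": {"mean": repr(ckpt.norm_stats.mean), "std": ckpt.norm_stats.std},
        "train_patient_ids": list(ckpt.train_patient_ids),
        "patient_ids": list(ckpt.latents.keys()),
    }
    arrays = {f"theta/{k}": v for k, v in ckpt.model.theta.items()}
    arrays.update({f"latent/{pid}": v for pid, v in ckpt.latents.items()})
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | pathlib.Path) -> Checkpoint:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        theta = {
            k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("theta/")
        }
        latents = LatentTable()
        for pid in header["patient_ids"]:
            latents[pid] = data[f"latent/{pid}"]
    config = ModelConfig(**header["model_config"])
    ns = header["norm_stats"]
    mean = complex(ns["mean"].strip("()")) if "j" in ns["mean"] else float(ns["mean"])
    return Checkpoint(
        model=INRModel(theta, config),
        latents=latents,
        norm_stats=NormStats(mean=mean, std=ns["std"]),
        train_patient_ids=tuple(header["train_patient_ids"]),
        version=header["version"],
    )
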