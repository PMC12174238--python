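"""NIfTI, mask-set, and configuration I/O.

Volumes are exchanged as NIfTI with a strictly axis-aligned, positive
affine; anything oblique, sheared or flipped is rejected rather than
silently reinterpreted.  Compartment sets travel as a single bit-encoded
integer label volume with a JSON sidecar mapping each role to its bit, so
overlapping roles (tumor inside liver, perfused splits) survive in one
file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields as dc_fields
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import CompartmentSet, ScalarVolume, VoxelGrid

_AFFINE_TOL = 1e-6


def _grid_from_affine(affine: np.ndarray, shape: tuple) -> VoxelGrid:
    lin = np.asarray(affine, dtype=float)[:3, :3]
    diag = np.diag(lin)
    off = lin - np.diag(diag)
    if np.abs(off).max() > _AFFINE_TOL * max(1.0, np.abs(diag).max()):
        raise ValueError(
            "oblique or sheared affine: only axis-aligned NIfTI volumes are supported"
        )
    if np.any(diag <= 0):
        raise ValueError(
            "affine with flipped or degenerate axes: spacings must be positive"
        )
    origin = np.asarray(affine, dtype=float)[:3, 3]
    return VoxelGrid(shape=tuple(shape), spacing_mm=tuple(diag), origin_mm=tuple(origin))


def _affine_from_grid(grid: VoxelGrid) -> np.ndarray:
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    affine[:3, 3] = grid.origin_mm
    return affine


def read_volume(path, quantity: str = "counts") -> ScalarVolume:
    """Read an axis-aligned NIfTI volume as a :class:`ScalarVolume`."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {data.ndim}-D data")
    grid = _grid_from_affine(img.affine, data.shape)
    if np.any(data < 0):
        raise ValueError(f"negative voxel values are invalid for {quantity}")
    return ScalarVolume(grid, data, quantity)


def write_volume(volume: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine_from_grid(volume.grid))
    nib.save(img, str(path))


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".roles.json")


def write_compartments(comp: CompartmentSet, path, sidecar=None) -> None:
    """Write masks as one bit-encoded label volume plus a role sidecar."""
    roles = sorted(comp.masks)
    if len(roles) > 30:
        raise ValueError("too many roles for bit encoding")
    bits = {role: 1 << i for i, role in enumerate(roles)}
    labels = np.zeros(comp.grid.shape, dtype=np.int32)
    for role, bit in bits.items():
        labels |= np.where(comp.masks[role], bit, 0).astype(np.int32)
    img = nib.Nifti1Image(labels, _affine_from_grid(comp.grid))
    nib.save(img, str(path))
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    sidecar.write_text(json.dumps({"encoding": "bitmask", "roles": bits}, indent=2))


def read_compartments(path, sidecar=None) -> CompartmentSet:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int64)
    grid = _grid_from_affine(img.affine, labels.shape)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    meta = json.loads(Path(sidecar).read_text())
    if meta.get("encoding") != "bitmask":
        raise ValueError("unsupported mask encoding; expected 'bitmask'")
    masks = {role: (labels & bit) > 0 for role, bit in meta["roles"].items()}
    return CompartmentSet(grid, masks)


def write_planar(image: np.ndarray, pixel_mm: tuple, path) -> None:
    """Store a 2-D planar count image as a thin NIfTI slab."""
    data = np.asarray(image, dtype=np.float64)[:, :, None]
    affine = np.diag([pixel_mm[0], pixel_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_planar(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError("planar images must be 2-D (or a single-slice slab)")
        data = data[:, :, 0]
    affine = np.asarray(img.affine)
    return data, (float(affine[0, 0]), float(affine[1, 1]))


def validated_config(raw: dict, allowed: set, context: str) -> dict:
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(
            f"unknown {context} config keys {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    return raw


def load_phantom_config(path) -> dict:
    """Load a phantom YAML config, rejecting unknown keys.

    Recognised keys are the :class:`~voxdose90.phantom.PhantomSpec` fields
    plus acquisition options ``counts_per_GBq``, ``noise``,
    ``spect_psf_fwhm_mm``, ``pet_psf_fwhm_mm`` and ``planar_pixel_mm``.
    """
    from .phantom import PhantomSpec

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("phantom config must be a mapping")
    spec_keys = {f.name for f in dc_fields(PhantomSpec)}
    acq_keys = {
        "counts_per_GBq",
        "noise",
        "spect_psf_fwhm_mm",
        "pet_psf_fwhm_mm",
        "planar_pixel_mm",
    }
    validated_config(raw, spec_keys | acq_keys, "phantom")
    return _tuplify(raw)


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(v) for v in obj)
    if isinstance(obj, dict):
        return {k: _tuplify(v) for k, v in obj.items()}
    return obj


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance(config: dict, seed) -> dict:
    from . import __version__

    return {
        "package": "voxdose90",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
    }


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_dvh_csv(dose_Gy: np.ndarray, volume_percent: np.ndarray, path) -> None:
    """Two-column CSV export of a cumulative DVH."""
    with open(path, "w") as fh:
        fh.write("dose_Gy,volume_percent\n")
        for d, v in zip(dose_Gy, volume_percent):
            fh.write(f"{d:.6g},{v:.6g}\n")
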