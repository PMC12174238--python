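"""Geometry-aware scalar volumes, compartment masks, and rigid resampling.

World coordinates are in millimetres on axis-aligned grids.  The origin of a
grid is the world position of the *center* of voxel (0, 0, 0); voxel ``(i, j,
k)`` is centred at ``origin + (i, j, k) * spacing``.  Axis 0 is left-right
(x), axis 1 anterior-posterior (y), axis 2 inferior-superior (z).  Oblique or
sheared orientations are deliberately unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

#: Recognised physical quantities carried by a :class:`ScalarVolume`.
QUANTITIES = ("counts", "activity_GBq", "dose_Gy")

#: Compartment roles used across the dosimetry and planning layers.
ROLES = (
    "whole_liver",
    "tumor",
    "normal_liver",
    "perfused",
    "perfused_tumor",
    "perfused_normal",
    "lungs",
)

_ORTHO_TOL = 1e-9


def _as_triple(value, name: str, cast=float) -> tuple:
    t = tuple(cast(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have exactly 3 entries, got {len(t)}")
    return t


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice in world (mm) coordinates.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis; every entry must be >= 1.
    spacing_mm : tuple of float
        Positive voxel edge lengths in mm.
    origin_mm : tuple of float, optional
        World position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple
    spacing_mm: tuple
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = _as_triple(self.shape, "shape", int)
        spacing = _as_triple(self.spacing_mm, "spacing_mm")
        origin = _as_triple(self.origin_mm, "origin_mm")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mL(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def axes(self) -> tuple:
        """Per-axis arrays of voxel-center world coordinates."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(3, *shape)``."""
        ax = self.axes()
        return np.stack(np.meshgrid(*ax, indexing="ij"))

    def extent_mm(self) -> tuple:
        """Physical bounding box ``(lo, hi)`` of the grid (voxel edges)."""
        lo = tuple(o - s / 2.0 for o, s in zip(self.origin_mm, self.spacing_mm))
        hi = tuple(
            o + (n - 0.5) * s
            for o, s, n in zip(self.origin_mm, self.spacing_mm, self.shape)
        )
        return lo, hi

    def covering(self, spacing_mm: Iterable[float]) -> "VoxelGrid":
        """A new grid with the given spacing covering this grid's extent.

        The new grid is centred on the old physical extent and enlarged to
        the next whole voxel along each axis.
        """
        spacing = _as_triple(spacing_mm, "spacing_mm")
        lo, hi = self.extent_mm()
        shape = tuple(
            int(np.ceil((h - l) / s - 1e-9)) for l, h, s in zip(lo, hi, spacing)
        )
        origin = tuple(
            (l + h) / 2.0 - (n - 1) * s / 2.0
            for l, h, s, n in zip(lo, hi, spacing, shape)
        )
        return VoxelGrid(shape=shape, spacing_mm=spacing, origin_mm=origin)

    def world_to_index(self, points_xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points of shape ``(3, ...)``."""
        pts = np.asarray(points_xyz, dtype=float)
        origin = np.asarray(self.origin_mm).reshape((3,) + (1,) * (pts.ndim - 1))
        spacing = np.asarray(self.spacing_mm).reshape((3,) + (1,) * (pts.ndim - 1))
        return (pts - origin) / spacing


@dataclass
class ScalarVolume:
    """A non-negative scalar field (counts, activity, or dose) on a grid."""

    grid: VoxelGrid
    values: np.ndarray
    quantity: str

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {values.shape} does not match grid {self.grid.shape}"
            )
        if self.quantity not in QUANTITIES:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; expected one of {QUANTITIES}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if np.any(values < 0):
            raise ValueError(f"{self.quantity} values must be non-negative")
        self.values = values

    def total(self) -> float:
        return float(self.values.sum())

    def with_values(self, values: np.ndarray, quantity: str | None = None) -> "ScalarVolume":
        return ScalarVolume(self.grid, values, quantity or self.quantity)


class CompartmentSet:
    """Named binary masks (tumor, perfused normal, ...) on a common grid.

    The recognised roles are listed in :data:`ROLES`; arbitrary extra labels
    are allowed.  Set identities (tumor inside liver, normal = liver minus
    tumor, perfused splits) can be verified with :meth:`check_identities`.
    """

    def __init__(self, grid: VoxelGrid, masks: Mapping[str, np.ndarray]):
        self.grid = grid
        self.masks: dict[str, np.ndarray] = {}
        for role, mask in masks.items():
            m = np.asarray(mask)
            if m.shape != tuple(grid.shape):
                raise ValueError(
                    f"mask {role!r} shape {m.shape} does not match grid {grid.shape}"
                )
            self.masks[str(role)] = m.astype(bool)

    @property
    def roles(self) -> tuple:
        return tuple(self.masks)

    def __contains__(self, role: str) -> bool:
        return role in self.masks

    def require(self, role: str, nonempty: bool = False) -> np.ndarray:
        if role not in self.masks:
            raise KeyError(
                f"unknown role {role!r}; available roles: {sorted(self.masks)}"
            )
        mask = self.masks[role]
        if nonempty and not mask.any():
            raise ValueError(f"role {role!r} has an empty mask")
        return mask

    def voxel_count(self, role: str) -> int:
        return int(self.require(role).sum())

    def volume_mL(self, role: str) -> float:
        return self.voxel_count(role) * self.grid.voxel_volume_mL

    def check_identities(self) -> None:
        """Verify the anatomical set identities among present roles.

        Raises ``ValueError`` on the first violated identity.  Only checks
        relations whose operand roles are all present.
        """
        m = self.masks
        checks = []
        if "tumor" in m and "whole_liver" in m:
            checks.append(("tumor ⊆ whole_liver", ~(m["tumor"] & ~m["whole_liver"]).any()))
        if {"normal_liver", "whole_liver", "tumor"} <= set(m):
            checks.append((
                "normal_liver = whole_liver \\ tumor",
                bool(np.array_equal(m["normal_liver"], m["whole_liver"] & ~m["tumor"])),
            ))
        if {"perfused_tumor", "perfused", "tumor"} <= set(m):
            checks.append((
                "perfused_tumor = perfused ∩ tumor",
                bool(np.array_equal(m["perfused_tumor"], m["perfused"] & m["tumor"])),
            ))
        if {"perfused_normal", "perfused", "normal_liver"} <= set(m):
            checks.append((
                "perfused_normal = perfused ∩ normal_liver",
                bool(np.array_equal(m["perfused_normal"], m["perfused"] & m["normal_liver"])),
            ))
        for name, ok in checks:
            if not ok:
                raise ValueError(f"compartment identity violated: {name}")


def compartment_volume_mL(comp: CompartmentSet, role: str) -> float:
    """Volume in mL of one compartment: voxel count times voxel volume."""
    return comp.volume_mL(role)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``x' = rotation @ x + translation_mm``."""

    rotation: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL * 10, rtol=0):
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation_mm", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler_zyx(
        cls, angles_deg: Iterable[float], translation_mm: Iterable[float] = (0, 0, 0)
    ) -> "RigidTransform":
        """Build from intrinsic Euler angles (degrees) applied in Z, Y, X order."""
        z, y, x = (float(a) for a in angles_deg)
        R = Rotation.from_euler("ZYX", [z, y, x], degrees=True).as_matrix()
        return cls(R, np.asarray(list(translation_mm), dtype=float))

    def apply(self, points_xyz: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_xyz, dtype=float)
        flat = pts.reshape(3, -1)
        out = self.rotation @ flat + self.translation_mm[:, None]
        return out.reshape(pts.shape)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation_mm + self.translation_mm,
        )


def _source_indices(
    transform: RigidTransform, source_grid: VoxelGrid, target_grid: VoxelGrid
) -> np.ndarray:
    # Pull-back: target voxel centers mapped through the inverse transform
    # into continuous source indices.
    inv = transform.inverse()
    world = target_grid.voxel_centers()
    src_world = inv.apply(world)
    return source_grid.world_to_index(src_world)


def resample(
    volume: ScalarVolume,
    transform: RigidTransform,
    target_grid: VoxelGrid,
    mode: str = "interpolate",
) -> ScalarVolume:
    """Resample a volume onto ``target_grid`` under a rigid transform.

    ``transform`` maps source-frame world coordinates into the target frame
    (e.g. the manual rigid registration taking a SPECT volume into the
    PET/MRI frame).  Values are sampled tri-linearly at transformed voxel
    centers; points falling outside the source field of view contribute
    zero signal.

    Parameters
    ----------
    mode : {"interpolate", "conserve_total"}
        ``conserve_total`` rescales the interpolated output so its sum
        equals the input sum — required when resampling counts or activity
        (the physical total must survive the grid change) and forbidden for
        dose, which is an intensive quantity.
    """
    if mode not in ("interpolate", "conserve_total"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    if mode == "conserve_total":
        if volume.quantity == "dose_Gy":
            raise ValueError(
                "non-conserved quantity: dose is intensive and must not be "
                "rescaled to conserve a total"
            )
        if volume.total() <= 0:
            raise ValueError("empty source: cannot conserve a zero total")
    coords = _source_indices(transform, volume.grid, target_grid)
    out = ndimage.map_coordinates(
        volume.values, coords, order=1, mode="constant", cval=0.0, prefilter=False
    )
    out = np.clip(out, 0.0, None)
    if mode == "conserve_total":
        total_out = out.sum()
        if total_out <= 0:
            raise ValueError(
                "resampled output has zero total; target grid does not "
                "intersect the source signal"
            )
        out *= volume.total() / total_out
    return ScalarVolume(target_grid, out, volume.quantity)


def resample_mask(
    mask: np.ndarray,
    source_grid: VoxelGrid,
    transform: RigidTransform,
    target_grid: VoxelGrid,
) -> np.ndarray:
    """Nearest-neighbour resampling for binary masks (order-preserving)."""
    m = np.asarray(mask)
    if m.shape != tuple(source_grid.shape):
        raise ValueError("mask shape does not match source grid")
    coords = _source_indices(transform, source_grid, target_grid)
    out = ndimage.map_coordinates(
        m.astype(np.float32), coords, order=0, mode="constant", cval=0.0
    )
    return out > 0.5


def resample_compartments(
    comp: CompartmentSet, transform: RigidTransform, target_grid: VoxelGrid
) -> CompartmentSet:
    masks = {
        role: resample_mask(mask, comp.grid, transform, target_grid)
        for role, mask in comp.masks.items()
    }
    return CompartmentSet(target_grid, masks)
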