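"""Rigid transforms and dense deformation fields.

A :class:`RigidTransform` maps world points (mm) as
``T(x) = R (x - center) + center + t`` with ``R`` built from Euler angles
(degrees, intrinsic x-y-z order).

A :class:`DeformationField` stores one 3-vector displacement ``u(x)`` in mm
per voxel of a *fixed* grid, with the pull-back convention: the location in
the moving image that corresponds to fixed-grid voxel ``x`` is ``x + u(x)``.
A zero field therefore resamples the moving image directly on the fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GridMismatchError
from .image_model import Grid


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid transform (rotation in degrees, translation in mm)."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation_deg", tuple(float(v) for v in self.rotation_deg))
        object.__setattr__(self, "translation_mm", tuple(float(v) for v in self.translation_mm))
        object.__setattr__(self, "center_mm", tuple(float(v) for v in self.center_mm))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        rot = self.rotation.as_matrix()
        c = np.asarray(self.center_mm)
        m[:3, :3] = rot
        m[:3, 3] = c + np.asarray(self.translation_mm) - rot @ c
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform points of shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts - c) @ self.rotation.as_matrix().T + c + t

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.inv()
        # Solve T_inv(T(x)) = x about the same center.
        t_inv = -(rot_inv.as_matrix() @ np.asarray(self.translation_mm))
        return RigidTransform(
            rotation_deg=tuple(rot_inv.as_euler("xyz", degrees=True)),
            translation_mm=tuple(t_inv),
            center_mm=self.center_mm,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform x -> self(other(x)), centered at self's center."""
        m = self.matrix() @ other.matrix()
        rot = Rotation.from_matrix(m[:3, :3])
        c = np.asarray(self.center_mm)
        t = m[:3, 3] - c + m[:3, :3] @ c
        return RigidTransform(
            rotation_deg=tuple(rot.as_euler("xyz", degrees=True)),
            translation_mm=tuple(t),
            center_mm=self.center_mm,
        )

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix(), np.eye(4), atol=tol))


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) on a fixed grid, pull-back convention."""

    displacements: np.ndarray  # (nx, ny, nz, 3) mm
    grid: Grid

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape != self.grid.shape + (3,):
            raise GridMismatchError(
                f"displacement shape {self.displacements.shape} "
                f"!= grid shape {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("deformation field contains non-finite values")

    @classmethod
    def zero(cls, grid: Grid) -> "DeformationField":
        return cls(np.zeros(grid.shape + (3,)), grid)

    def target_points(self) -> np.ndarray:
        """World coordinates x + u(x) for every fixed-grid voxel, (nx,ny,nz,3)."""
        coords = np.moveaxis(self.grid.world_coordinates(), 0, -1)
        return coords + self.displacements

    @property
    def max_magnitude_mm(self) -> float:
        return float(np.linalg.norm(self.displacements, axis=-1).max())
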