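"""Volumetric data types, grid geometry, and NIfTI-backed I/O.

Conventions
-----------
* Voxel arrays are indexed ``[i, j, k]``; index ``(i, j, k)`` sits at world
  coordinate ``origin + index * spacing`` (millimetres, 0-based, axis-aligned).
* Only axis-aligned volumes are supported: the NIfTI affine must be diagonal
  with strictly positive spacings.
* Surfaces are voxel-center point sets: a surface voxel is a foreground voxel
  with at least one background 6-neighbour, where the grid border counts as
  background.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import (
    EmptyStructureError,
    GridMismatchError,
    UnsupportedOrientationError,
)

MODALITIES = ("PCT", "CTOR", "CBCT")
ORGANS = ("bladder", "rectum")


@dataclass(frozen=True)
class Grid:
    """Axis-aligned voxel grid geometry (shape, spacing and origin in mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of fractional voxel indices, shape (..., 3)."""
        return self.origin_arr + np.asarray(index, dtype=float) * self.spacing_arr

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (mm), shape (..., 3)."""
        return (np.asarray(points, dtype=float) - self.origin_arr) / self.spacing_arr

    def world_coordinates(self) -> np.ndarray:
        """Dense array of voxel-center world coordinates, shape (3, nx, ny, nz)."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def center_world(self) -> np.ndarray:
        return self.index_to_world((np.asarray(self.shape, dtype=float) - 1) / 2.0)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ImageVolume:
    """A 3D scalar image (HU-like intensities) on an axis-aligned grid."""

    voxels: np.ndarray
    grid: Grid
    modality: str = "PCT"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if tuple(self.voxels.shape) != self.grid.shape:
            raise GridMismatchError(
                f"voxel shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin


@dataclass
class StructureMask:
    """A binary organ mask living on the grid of its image."""

    mask: np.ndarray
    grid: Grid
    organ: str = "bladder"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if tuple(self.mask.shape) != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3

    def is_empty(self) -> bool:
        return not self.mask.any()


@dataclass
class SurfacePointSet:
    """World-coordinate centers (mm) of the boundary voxels of a mask."""

    points: np.ndarray  # (n, 3) mm
    organ: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.points.shape[0]


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean array of boundary voxels under 6-connectivity.

    A voxel is on the boundary if it is foreground and at least one of its six
    face neighbours is background; voxels outside the grid count as background.
    """
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = np.ones_like(m)
    for axis in range(3):
        for shift in (-1, 1):
            interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    return m & ~interior


def extract_surface(mask: StructureMask) -> SurfacePointSet:
    """Surface voxel centers of a mask as world points in mm.

    Raises :class:`EmptyStructureError` for an empty mask.
    """
    if mask.is_empty():
        raise EmptyStructureError(f"mask for organ {mask.organ!r} is empty")
    idx = np.argwhere(boundary_voxels(mask.mask))
    return SurfacePointSet(points=mask.grid.index_to_world(idx), organ=mask.organ)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

_AXIS_ALIGN_TOL = 1e-4


def _grid_from_affine(affine: np.ndarray, shape: Sequence[int]) -> Grid:
    rot = np.asarray(affine, dtype=float)[:3, :3]
    diag = np.diag(rot)
    off = rot - np.diag(diag)
    scale = max(np.abs(rot).max(), 1.0)
    if np.abs(off).max() > _AXIS_ALIGN_TOL * scale or np.any(diag <= 0):
        raise UnsupportedOrientationError(
            "only axis-aligned NIfTI volumes with positive spacings are supported"
        )
    return Grid(shape=tuple(shape), spacing=tuple(diag), origin=tuple(affine[:3, 3]))


def read_volume(path: str | Path, modality: str = "PCT") -> ImageVolume:
    """Read an axis-aligned NIfTI-1 volume.

    Spacing and origin are taken from the (diagonal) affine; integer voxel
    data are preserved losslessly.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise UnsupportedOrientationError("only 3D volumes are supported")
    grid = _grid_from_affine(img.affine, data.shape)
    return ImageVolume(voxels=data, grid=grid, modality=modality)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine."""
    img = nib.Nifti1Image(np.asarray(volume.voxels), volume.grid.affine())
    nib.save(img, str(path))


def read_mask(path: str | Path, organ: str = "bladder") -> StructureMask:
    """Read a 0/1 uint8 NIfTI mask."""
    vol = read_volume(path)
    return StructureMask(mask=vol.voxels > 0, grid=vol.grid, organ=organ)


def write_mask(mask: StructureMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Study manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "patient_id",
    "fraction",
    "modality",
    "role",
    "image",
    "bladder_mask",
    "rectum_mask",
)


@dataclass
class ManifestRow:
    patient_id: str
    fraction: int
    modality: str
    role: str  # "reference" or "fraction"
    image: str
    bladder_mask: str = ""
    rectum_mask: str = ""

    @property
    def is_reference(self) -> bool:
        return self.role == "reference"

    @property
    def has_masks(self) -> bool:
        return bool(self.bladder_mask) and bool(self.rectum_mask)


@dataclass
class StudyManifest:
    """Table of (patient, fraction, modality) image/mask paths.

    Exactly one reference (planning) entry per patient; fraction indices are
    unique within a patient.
    """

    rows: list[ManifestRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for pid in self.patients():
            refs = [r for r in self.rows if r.patient_id == pid and r.is_reference]
            if len(refs) != 1:
                raise ValueError(
                    f"patient {pid!r} has {len(refs)} reference entries (need 1)"
                )
            fracs = [
                r.fraction
                for r in self.rows
                if r.patient_id == pid and not r.is_reference
            ]
            if len(fracs) != len(set(fracs)):
                raise ValueError(f"patient {pid!r} has duplicate fraction indices")
            if any(f < 1 for f in fracs):
                raise ValueError("fraction indices must be >= 1")

    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def reference(self, patient_id: str) -> ManifestRow:
        return next(
            r for r in self.rows if r.patient_id == patient_id and r.is_reference
        )

    def fractions(self, patient_id: str) -> list[ManifestRow]:
        return sorted(
            (r for r in self.rows if r.patient_id == patient_id and not r.is_reference),
            key=lambda r: r.fraction,
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(MANIFEST_COLUMNS)
            for r in self.rows:
                writer.writerow(
                    [
                        r.patient_id,
                        r.fraction,
                        r.modality,
                        r.role,
                        r.image,
                        r.bladder_mask,
                        r.rectum_mask,
                    ]
                )

    @classmethod
    def load(cls, path: str | Path) -> "StudyManifest":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(
                    ManifestRow(
                        patient_id=rec["patient_id"],
                        fraction=int(rec["fraction"]),
                        modality=rec["modality"],
                        role=rec["role"],
                        image=rec["image"],
                        bladder_mask=rec.get("bladder_mask", "") or "",
                        rectum_mask=rec.get("rectum_mask", "") or "",
                    )
                )
        return cls(rows=rows)
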