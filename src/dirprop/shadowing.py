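"""Shadowed-NIB contour propagation.

The interiors of the delineated organs are contrast-boosted (by default a
+700 HU shift, raising soft tissue to bone-like density) on BOTH the fraction
image (using its manual contours) and the planning CT (using the planning
contours); rigid and NIB free-form registration are then run on the enhanced
pair, and the resulting deformation field is used to propagate the ORIGINAL
planning contours. Enhancing both sides keeps the intensity-matching
objective consistent: the boosted interiors correspond across the two images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AmbiguousMaskError, GridMismatchError, SchedulingError
from .image_model import ImageVolume, StructureMask
from .registration import (
    FFDOptions,
    RegistrationResult,
    RigidOptions,
    register_nib,
    register_rigid,
)
from .transforms import RigidTransform

DEFAULT_SHADOW_HU = 700.0  # lifts organ interiors to bone-like density


def shadow_enhance(
    image: ImageVolume,
    masks: dict[str, StructureMask] | list[StructureMask],
    shift_mode: str = "add",
    value: float = DEFAULT_SHADOW_HU,
) -> ImageVolume:
    """Contrast-enhance organ interiors by adding (or setting) an HU value.

    Only voxels inside the masks change; masks must be pairwise disjoint and
    live on the image grid. Returns a new volume.
    """
    mask_list = list(masks.values()) if isinstance(masks, dict) else list(masks)
    combined = np.zeros(image.grid.shape, dtype=np.int8)
    for m in mask_list:
        if m.grid != image.grid:
            raise GridMismatchError(f"mask {m.organ!r} is not on the image grid")
        combined += m.mask
    if np.any(combined > 1):
        raise AmbiguousMaskError("organ masks overlap; shadow enhancement is ambiguous")
    interior = combined > 0

    voxels = np.asarray(image.voxels, dtype=np.float32).copy()
    if shift_mode == "add":
        voxels[interior] += value
    elif shift_mode == "set":
        voxels[interior] = value
    else:
        raise ValueError(f"shift_mode must be 'add' or 'set', got {shift_mode!r}")
    return ImageVolume(voxels=voxels, grid=image.grid, modality=image.modality)


@dataclass(frozen=True)
class ShadowOptions:
    shift_mode: str = "add"
    value: float = DEFAULT_SHADOW_HU


def run_shadowed_nib(
    planning: ImageVolume,
    planning_masks: dict[str, StructureMask],
    fraction: ImageVolume,
    fraction_masks: dict[str, StructureMask],
    ffd_options: FFDOptions | None = None,
    rigid_options: RigidOptions | None = None,
    shadow: ShadowOptions | None = None,
    rigid: RigidTransform | None = None,
) -> RegistrationResult:
    """Shadowed-NIB registration between a fraction and the planning CT.

    Both images are shadow-enhanced with their own (manual) contours, rigid
    registration is run (unless a precomputed ``rigid`` is supplied), and NIB
    free-form registration follows on the enhanced pair. The returned result
    is meant for propagating the original, unenhanced planning contours.

    Raises :class:`SchedulingError` when the fraction lacks manual masks.
    """
    if not fraction_masks or any(m.is_empty() for m in fraction_masks.values()):
        raise SchedulingError(
            f"fraction {getattr(fraction, 'modality', '?')} has no manual masks; "
            "shadowed-NIB requires them"
        )
    shadow = shadow or ShadowOptions()
    enhanced_fraction = shadow_enhance(fraction, fraction_masks, shadow.shift_mode, shadow.value)
    enhanced_planning = shadow_enhance(planning, planning_masks, shadow.shift_mode, shadow.value)
    if rigid is None:
        rigid = register_rigid(enhanced_fraction, enhanced_planning, rigid_options)
    return register_nib(enhanced_fraction, enhanced_planning, ffd_options, rigid=rigid)
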