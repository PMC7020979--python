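"""Carrying reference contours onto a fraction grid via a registration result.

The mask is pulled back in a single interpolation pass: every fixed-grid
voxel is mapped to moving-image space through ``T_rigid(x + u(x))``, the 0/1
mask is sampled there with trilinear interpolation, and the result is
thresholded at 0.5.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError
from .image_model import Grid, StructureMask
from .registration import RegistrationResult
from .transforms import DeformationField, RigidTransform


def propagate_mask(
    mask: StructureMask,
    result: RegistrationResult,
    fixed_grid: Grid,
) -> StructureMask:
    """Propagate a moving-grid mask onto the fixed grid.

    ``result.dvf`` may be ``None`` for rigid-only propagation. The DVF, when
    present, must live on ``fixed_grid``.
    """
    if result.dvf is not None and result.dvf.grid != fixed_grid:
        raise GridMismatchError("deformation field is not defined on the fixed grid")

    pts = np.moveaxis(fixed_grid.world_coordinates(), 0, -1)
    if result.dvf is not None:
        pts = pts + result.dvf.displacements
    pts = result.rigid.apply(pts.reshape(-1, 3))
    idx = mask.grid.world_to_index(pts)
    # samples within half a voxel of the border clamp onto it, so a border
    # slice is not lost to an epsilon overshoot; farther out is background
    for axis, n in enumerate(mask.grid.shape):
        col = idx[:, axis]
        np.copyto(col, 0.0, where=(col < 0.0) & (col > -0.5))
        np.copyto(col, n - 1.0, where=(col > n - 1.0) & (col < n - 0.5))
    sampled = ndimage.map_coordinates(
        mask.mask.astype(np.float32), idx.T, order=1, mode="constant", cval=0.0
    ).reshape(fixed_grid.shape)
    return StructureMask(sampled >= 0.5, fixed_grid, organ=mask.organ)


def result_from_ground_truth(
    dvf_pullback: DeformationField,
) -> RegistrationResult:
    """Wrap a known total pull-back field as a registration result.

    The rigid part is the identity because the stored field already includes
    any setup transform.
    """
    return RegistrationResult(
        rigid=RigidTransform(),
        dvf=dvf_pullback,
        final_objective=0.0,
        objective_history=[],
        iterations=[],
        converged=True,
    )
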