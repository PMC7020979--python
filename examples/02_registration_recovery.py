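"""Recover a known setup error and organ deformation from phantom images.

Applies a known rigid offset plus bladder/rectum filling to a phantom
fraction, then runs rigid + normalized-intensity free-form registration and
measures how well the known answer is recovered.
"""

import numpy as np

from dirprop.metrics import dice
from dirprop.phantom import PhantomConfig, make_fraction, make_planning_phantom
from dirprop.propagation import propagate_mask
from dirprop.registration import register_nib, register_rigid
from dirprop.transforms import RigidTransform

planning = make_planning_phantom(PhantomConfig(seed=3))
setup = RigidTransform((0.5, -0.4, 1.0), (3.0, -2.0, 4.0),
                       tuple(planning.grid.center_world))
img, gt = make_fraction(
    planning, 1, np.random.default_rng(7), modality="CTOR",
    filling={"bladder": 1.4, "rectum": 1.25}, setup=setup,
)

rigid = register_rigid(img, planning.image)
inv = setup.inverse()
err = np.abs(np.subtract(rigid.translation_mm, inv.translation_mm)).max()
print(f"true pull-back translation : {np.round(inv.translation_mm, 2)} mm")
print(f"recovered translation      : {np.round(rigid.translation_mm, 2)} mm")
print(f"worst axis error           : {err:.3f} mm")

result = register_nib(img, planning.image, rigid=rigid)
for organ in ("bladder", "rectum"):
    prop_rigid = propagate_mask(planning.masks[organ], type(result)(rigid, None, 0.0),
                                img.grid)
    prop_nib = propagate_mask(planning.masks[organ], result, img.grid)
    print(f"{organ:8s} DSC vs truth: rigid-only {dice(gt.masks[organ], prop_rigid):.3f}"
          f" -> free-form {dice(gt.masks[organ], prop_nib):.3f}")
# The free-form stage recovers the organ filling the rigid stage cannot:
# DSC rises toward 1 as the propagated contour tracks the deformed organ.
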