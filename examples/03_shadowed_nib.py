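"""Shadowed-NIB contour propagation on a low-contrast CBCT fraction.

On CBCT-like guidance the bladder barely stands out from surrounding soft
tissue, so plain intensity-driven registration struggles. Boosting the
delineated organ interiors by +700 HU (bone-like density) on both the
fraction and the planning CT gives the registration an unmistakable target.
"""

import numpy as np

from dirprop.metrics import dice
from dirprop.phantom import PhantomConfig, make_fraction, make_planning_phantom
from dirprop.propagation import propagate_mask
from dirprop.registration import register_nib, register_rigid
from dirprop.shadowing import run_shadowed_nib

planning = make_planning_phantom(PhantomConfig(seed=9))
img, gt = make_fraction(planning, 1, np.random.default_rng(3), modality="CBCT")

rigid = register_rigid(img, planning.image)
plain = register_nib(img, planning.image, rigid=rigid)
shadowed = run_shadowed_nib(planning.image, planning.masks, img, gt.masks,
                            rigid=rigid)

print(f"bladder fill {gt.filling['bladder']:.2f}, "
      f"rectum fill {gt.filling['rectum']:.2f} (CBCT appearance)")
for organ in ("bladder", "rectum"):
    d_plain = dice(gt.masks[organ],
                   propagate_mask(planning.masks[organ], plain, img.grid))
    d_shadow = dice(gt.masks[organ],
                    propagate_mask(planning.masks[organ], shadowed, img.grid))
    print(f"{organ:8s} DSC: plain NIB {d_plain:.3f}  ->  shadowed NIB {d_shadow:.3f}")
# Shadowed NIB should clearly win on both organs: the +700 HU interiors
# dominate the matching objective where the raw CBCT contrast is too weak.
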