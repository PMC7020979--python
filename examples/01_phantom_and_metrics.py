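"""Build a synthetic pelvic phantom fraction and score contour similarity.

Generates a planning phantom, spawns one fraction with a +40% bladder fill,
and compares the (deliberately unaligned) planning bladder contour with the
fraction's true bladder using all four similarity metrics.
"""

import numpy as np

from dirprop.metrics import evaluate_pair
from dirprop.phantom import PhantomConfig, make_fraction, make_planning_phantom

planning = make_planning_phantom(PhantomConfig(seed=1))
img, gt = make_fraction(
    planning, 1, np.random.default_rng(2), modality="CTOR",
    filling={"bladder": 1.4, "rectum": 1.0},
)

rec = evaluate_pair(gt.masks["bladder"], planning.masks["bladder"],
                    patient_id="P01", fraction=1, algorithm="rigid_only")
print(f"bladder fill factor: {gt.filling['bladder']:.2f}")
print(f"HD  = {rec.hd_mm:6.2f} mm   (largest surface mismatch)")
print(f"MDA = {rec.mda_mm:6.2f} mm   (mean surface mismatch)")
print(f"DSC = {rec.dsc:6.3f}      (volume overlap, 1 = identical)")
print(f"JI  = {rec.jaccard:6.3f}      (stricter overlap ratio; always <= DSC)")
# The un-propagated planning contour misses the filled bladder: distances of
# a few mm and overlap well below 1 quantify exactly how much contouring
# would be wrong without deformable propagation.
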