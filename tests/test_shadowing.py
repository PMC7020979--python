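"""Shadow enhancement and the shadowed-NIB propagation procedure."""

import numpy as np
import pytest

from dirprop.errors import AmbiguousMaskError, SchedulingError
from dirprop.image_model import Grid, ImageVolume, StructureMask
from dirprop.metrics import dice
from dirprop.phantom import make_fraction
from dirprop.propagation import propagate_mask
from dirprop.registration import register_nib, register_rigid
from dirprop.shadowing import ShadowOptions, run_shadowed_nib, shadow_enhance
from dirprop.transforms import RigidTransform

from conftest import FAST_FFD


def small_image_with_masks(rng):
    g = Grid((10, 10, 8), (2.0, 2.0, 3.0))
    img = ImageVolume(rng.normal(40.0, 10.0, g.shape).astype(np.float32), g, "CTOR")
    b = np.zeros(g.shape, bool)
    b[2:5, 2:5, 2:5] = True
    r = np.zeros(g.shape, bool)
    r[6:9, 6:9, 2:5] = True
    masks = {
        "bladder": StructureMask(b, g, organ="bladder"),
        "rectum": StructureMask(r, g, organ="rectum"),
    }
    return img, masks


class TestShadowEnhance:
    def test_add_mode_shifts_only_interior(self, rng):
        img, masks = small_image_with_masks(rng)
        out = shadow_enhance(img, masks, "add", 700.0)
        interior = masks["bladder"].mask | masks["rectum"].mask
        assert np.allclose(out.voxels[interior], img.voxels[interior] + 700.0)
        assert np.array_equal(out.voxels[~interior], img.voxels[~interior])
        # the input volume is untouched
        assert not np.shares_memory(out.voxels, img.voxels)

    def test_set_mode(self, rng):
        img, masks = small_image_with_masks(rng)
        out = shadow_enhance(img, masks, "set", 700.0)
        interior = masks["bladder"].mask | masks["rectum"].mask
        assert np.all(out.voxels[interior] == 700.0)

    def test_mean_shift_is_exact(self, rng):
        img, masks = small_image_with_masks(rng)
        out = shadow_enhance(img, masks, "add", 700.0)
        m = masks["bladder"].mask
        assert out.voxels[m].mean() - img.voxels[m].mean() == pytest.approx(700.0)
        outside = ~(masks["bladder"].mask | masks["rectum"].mask)
        assert out.voxels[outside].mean() == img.voxels[outside].mean()

    def test_empty_masks_leave_image_unchanged(self, rng):
        img, masks = small_image_with_masks(rng)
        g = img.grid
        empty = {"bladder": StructureMask(np.zeros(g.shape, bool), g)}
        out = shadow_enhance(img, empty)
        assert np.array_equal(out.voxels, img.voxels)

    def test_overlapping_masks_rejected(self, rng):
        img, masks = small_image_with_masks(rng)
        masks["rectum"] = StructureMask(masks["bladder"].mask.copy(), img.grid, "rectum")
        with pytest.raises(AmbiguousMaskError):
            shadow_enhance(img, masks)


class TestShadowedNib:
    def test_missing_manual_masks_raise_scheduling_error(self, planning):
        g = planning.grid
        empty = {
            "bladder": StructureMask(np.zeros(g.shape, bool), g, "bladder"),
        }
        with pytest.raises(SchedulingError):
            run_shadowed_nib(
                planning.image, planning.masks, planning.image, empty,
                ffd_options=FAST_FFD,
            )

    def test_identity_fraction_propagates_perfectly(self, default_config):
        # geometrically identical pair, appearance noise off: registration
        # must return an (essentially) zero field and perfect contours
        from dataclasses import replace

        from dirprop.phantom import make_planning_phantom

        planning = make_planning_phantom(replace(default_config, noise_sd=0.0))
        img, gt = make_fraction(
            planning, 1, np.random.default_rng(2), modality="CTOR",
            filling={"bladder": 1.0, "rectum": 1.0},
            setup=RigidTransform(center_mm=tuple(planning.grid.center_world)),
            noise_sd=0.0,
        )
        res = run_shadowed_nib(
            planning.image, planning.masks, img, gt.masks, ffd_options=FAST_FFD
        )
        for organ in ("bladder", "rectum"):
            prop = propagate_mask(planning.masks[organ], res, img.grid)
            assert dice(prop, gt.masks[organ]) >= 0.99

    def test_zero_shift_equals_plain_nib_bitwise(self, planning):
        img, gt = make_fraction(
            planning, 1, np.random.default_rng(9), modality="CTOR",
            filling={"bladder": 1.2, "rectum": 1.1},
        )
        rigid = register_rigid(img, planning.image)
        plain = register_nib(img, planning.image, FAST_FFD, rigid=rigid)
        shadowed = run_shadowed_nib(
            planning.image, planning.masks, img, gt.masks,
            ffd_options=FAST_FFD, shadow=ShadowOptions(value=0.0), rigid=rigid,
        )
        assert np.array_equal(
            plain.dvf.displacements, shadowed.dvf.displacements
        )

    def test_shadowing_beats_plain_nib_on_low_contrast_fill(self, planning):
        # CBCT appearance plus a large bladder fill: the enhanced interiors
        # give the registration the contrast the raw CBCT lacks
        img, gt = make_fraction(
            planning, 1, np.random.default_rng(21), modality="CBCT",
            filling={"bladder": 1.4, "rectum": 1.0},
        )
        rigid = register_rigid(img, planning.image)
        plain = register_nib(img, planning.image, FAST_FFD, rigid=rigid)
        shadowed = run_shadowed_nib(
            planning.image, planning.masks, img, gt.masks,
            ffd_options=FAST_FFD, rigid=rigid,
        )
        d_plain = dice(gt.masks["bladder"],
                       propagate_mask(planning.masks["bladder"], plain, img.grid))
        d_shadow = dice(gt.masks["bladder"],
                        propagate_mask(planning.masks["bladder"], shadowed, img.grid))
        assert d_shadow > d_plain
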