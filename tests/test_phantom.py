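"""Synthetic phantom: geometry, ground truth, appearance models, schedules."""

import numpy as np
import pytest
from scipy import ndimage

from dirprop.errors import GeometryError
from dirprop.image_model import StructureMask
from dirprop.metrics import dice
from dirprop.phantom import (
    CBCTModel,
    PhantomConfig,
    make_fraction,
    make_planning_phantom,
    make_study,
    manual_fractions,
)
from dirprop.transforms import RigidTransform


def identity_setup(planning):
    return RigidTransform(center_mm=tuple(planning.grid.center_world))


class TestPlanningPhantom:
    def test_masks_disjoint_and_nonempty(self, planning):
        b, r = planning.masks["bladder"], planning.masks["rectum"]
        assert not b.is_empty() and not r.is_empty()
        assert not (b.mask & r.mask).any()

    def test_same_seed_is_bitwise_identical(self, default_config):
        a = make_planning_phantom(default_config)
        b = make_planning_phantom(default_config)
        assert np.array_equal(a.image.voxels, b.image.voxels)
        assert np.array_equal(a.masks["bladder"].mask, b.masks["bladder"].mask)

    def test_bladder_volume_matches_analytic_ellipsoid(self, planning, default_config):
        a, b, c = default_config.bladder_semi_axes_mm
        analytic = 4.0 / 3.0 * np.pi * a * b * c
        assert planning.masks["bladder"].volume_mm3 == pytest.approx(analytic, rel=0.05)

    def test_oversized_organ_raises_geometry_error(self):
        cfg = PhantomConfig(bladder_semi_axes_mm=(80.0, 60.0, 60.0))
        with pytest.raises(GeometryError):
            make_planning_phantom(cfg)


class TestFractionGeneration:
    def test_identity_fraction_equals_noise_free_planning(self):
        cfg = PhantomConfig(seed=4, noise_sd=0.0)
        p = make_planning_phantom(cfg)
        img, gt = make_fraction(
            p, 1, np.random.default_rng(0), modality="CTOR",
            filling={"bladder": 1.0, "rectum": 1.0}, setup=identity_setup(p),
            noise_sd=0.0,
        )
        assert np.allclose(img.voxels, p.image.voxels, atol=1e-3)
        assert gt.dvf_pullback.max_magnitude_mm < 1e-9

    def test_bladder_filling_scales_true_volume(self, planning):
        img, gt = make_fraction(
            planning, 1, np.random.default_rng(1), modality="CTOR",
            filling={"bladder": 1.5, "rectum": 1.0}, setup=identity_setup(planning),
        )
        ratio = gt.masks["bladder"].voxel_count / planning.masks["bladder"].voxel_count
        assert ratio == pytest.approx(1.5, rel=0.05)

    def test_cbct_gain_offset_on_bone(self):
        cfg = PhantomConfig(
            seed=4, cbct_model=CBCTModel(gain=0.8, offset=-30.0, noise_sd=5.0,
                                         bias_amplitude=0.0),
        )
        p = make_planning_phantom(cfg)
        img, _ = make_fraction(
            p, 1, np.random.default_rng(2), modality="CBCT",
            filling={"bladder": 1.0, "rectum": 1.0}, setup=identity_setup(p),
        )
        pts = np.moveaxis(p.grid.world_coordinates(), 0, -1)
        bone = p.anatomy.in_bone(pts) & p.anatomy.in_body(pts)
        expected = 0.8 * p.clean_hu[bone].mean() - 30.0
        assert img.voxels[bone].mean() == pytest.approx(expected, abs=3.0)

    def test_stored_deformation_reproduces_true_masks(self, planning):
        img, gt = make_fraction(
            planning, 1, np.random.default_rng(3), modality="CTOR",
            filling={"bladder": 1.4, "rectum": 0.8},
        )
        tgt = gt.dvf_pullback.target_points()
        idx = planning.grid.world_to_index(tgt.reshape(-1, 3))
        for organ in ("bladder", "rectum"):
            warped = ndimage.map_coordinates(
                planning.masks[organ].mask.astype(np.float32), idx.T,
                order=1, mode="constant",
            ).reshape(planning.grid.shape) >= 0.5
            d = dice(StructureMask(warped, planning.grid, organ=organ), gt.masks[organ])
            assert d >= 0.99

    def test_bone_stays_rigid_under_filling(self, planning):
        img, gt = make_fraction(
            planning, 1, np.random.default_rng(4), modality="CTOR",
            filling={"bladder": 1.5, "rectum": 1.3}, setup=identity_setup(planning),
        )
        pts = np.moveaxis(planning.grid.world_coordinates(), 0, -1)
        bone = planning.anatomy.in_bone(pts) & planning.anatomy.in_body(pts)
        u = gt.dvf_pullback.displacements[bone]
        centroid_shift = np.linalg.norm(u.mean(axis=0))
        assert centroid_shift < 0.5 * min(planning.grid.spacing)

    def test_extreme_filling_raises_geometry_error(self, planning):
        with pytest.raises(GeometryError):
            make_fraction(
                planning, 1, np.random.default_rng(5),
                filling={"bladder": 40.0, "rectum": 1.0},
            )


class TestSchedules:
    def test_daily_covers_all_fractions(self):
        assert manual_fractions("daily", 10) == list(range(1, 11))

    def test_first5_then_weekly(self):
        assert manual_fractions("first5_then_weekly", 23) == [1, 2, 3, 4, 5, 10, 15, 20]


class TestStudyGeneration:
    @pytest.fixture(scope="class")
    def tiny_config(self):
        # coarse grid keeps the on-disk study small and fast
        return PhantomConfig(shape=(16, 16, 12), spacing=(8.0, 8.0, 10.0),
                             n_fractions=10, seed=11)

    def test_single_patient_daily_manifest(self, tiny_config, tmp_path_factory):
        out = tmp_path_factory.mktemp("study1")
        manifest = make_study(tiny_config, 1, 0, out)
        rows = manifest.fractions("P01")
        assert len(rows) == 10
        assert all(r.has_masks for r in rows)
        assert manifest.reference("P01").modality == "PCT"
        assert (out / "manifest.csv").exists()

    def test_weekly_schedule_marks_expected_fractions(self, tmp_path_factory):
        cfg = PhantomConfig(shape=(16, 16, 12), spacing=(8.0, 8.0, 10.0),
                            n_fractions=12, seed=11)
        out = tmp_path_factory.mktemp("study2")
        manifest = make_study(cfg, 2, 0, out)  # second CTOR patient is weekly
        weekly = manifest.fractions("P02")
        contoured = [r.fraction for r in weekly if r.has_masks]
        assert contoured == [1, 2, 3, 4, 5, 10]

    def test_full_cohort_scale_matches_study(self, tmp_path_factory):
        # 20 patients x 23 fractions ~ the ~453 analyzed fractions
        cfg = PhantomConfig(shape=(16, 16, 12), spacing=(8.0, 8.0, 10.0),
                            n_fractions=23, seed=2)
        out = tmp_path_factory.mktemp("study3")
        manifest = make_study(cfg, 10, 10, out)
        n_fraction_rows = sum(len(manifest.fractions(p)) for p in manifest.patients())
        assert n_fraction_rows == 460
        assert abs(n_fraction_rows - 453) / 453 < 0.1
        modalities = {r.modality for r in manifest.rows if not r.is_reference}
        assert modalities == {"CTOR", "CBCT"}

    def test_study_is_deterministic(self, tiny_config, tmp_path_factory):
        out1 = tmp_path_factory.mktemp("det1")
        out2 = tmp_path_factory.mktemp("det2")
        make_study(tiny_config, 1, 1, out1)
        make_study(tiny_config, 1, 1, out2)
        from dirprop.image_model import read_volume

        a = read_volume(out1 / "P02" / "fraction_03.nii.gz")
        b = read_volume(out2 / "P02" / "fraction_03.nii.gz")
        assert np.array_equal(a.voxels, b.voxels)
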