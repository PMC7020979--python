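"""Contour similarity metrics against analytic cases and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from dirprop.errors import EmptyStructureError, GridMismatchError, UndefinedMetricError
from dirprop.image_model import Grid, StructureMask, extract_surface
from dirprop.metrics import (
    dice,
    evaluate_pair,
    hausdorff,
    jaccard,
    mean_distance_to_agreement,
)

from conftest import random_blob_mask


def brute_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def brute_mda(a: np.ndarray, b: np.ndarray) -> float:
    d = cdist(a, b)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(pooled.mean())


def cube_pair():
    """10x10x10 cubes overlapping in a 5x10x10 slab (the analytic DSC=0.5 case)."""
    g = Grid((15, 10, 10), (1.0, 1.0, 1.0))
    a = np.zeros(g.shape, bool)
    b = np.zeros(g.shape, bool)
    a[0:10] = True
    b[5:15] = True
    return StructureMask(a, g), StructureMask(b, g)


class TestAnalyticCases:
    def test_identical_sets_have_zero_distances(self, rng):
        pts = rng.uniform(0, 10, size=(40, 3))
        assert hausdorff(pts, pts) == 0.0
        assert mean_distance_to_agreement(pts, pts) == 0.0

    def test_three_four_five_pair(self):
        assert hausdorff(np.array([[0.0, 0.0, 0.0]]), np.array([[3.0, 4.0, 0.0]])) == 5.0

    def test_mda_single_pair(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[2.0, 0.0, 0.0]])
        assert mean_distance_to_agreement(a, b) == 2.0

    def test_overlapping_cubes_dice_half_jaccard_third(self):
        v1, v2 = cube_pair()
        assert dice(v1, v2) == pytest.approx(0.5)
        assert jaccard(v1, v2) == pytest.approx(1.0 / 3.0)

    def test_identical_and_disjoint_masks(self):
        g = Grid((8, 8, 8), (1.0, 1.0, 1.0))
        a = np.zeros(g.shape, bool)
        a[:3] = True
        b = np.zeros(g.shape, bool)
        b[5:] = True
        ma, mb = StructureMask(a, g), StructureMask(b, g)
        assert dice(ma, ma) == 1.0 and jaccard(ma, ma) == 1.0
        assert dice(ma, mb) == 0.0 and jaccard(ma, mb) == 0.0


class TestOracles:
    def test_hausdorff_and_mda_match_brute_force_on_random_point_sets(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 50, size=(200, 3))
            b = rng.uniform(0, 50, size=(180, 3))
            assert hausdorff(a, b) == pytest.approx(brute_hausdorff(a, b), abs=1e-9)
            assert mean_distance_to_agreement(a, b) == pytest.approx(
                brute_mda(a, b), abs=1e-9
            )

    def test_surface_distances_match_brute_force_on_random_masks(self, rng):
        g = Grid((14, 13, 12), (0.98, 0.98, 3.0))
        for _ in range(15):
            m1 = StructureMask(random_blob_mask(g.shape, rng), g)
            m2 = StructureMask(random_blob_mask(g.shape, rng), g)
            a = extract_surface(m1).points
            b = extract_surface(m2).points
            assert hausdorff(a, b) == pytest.approx(brute_hausdorff(a, b), abs=1e-9)
            assert mean_distance_to_agreement(a, b) == pytest.approx(
                brute_mda(a, b), abs=1e-9
            )


class TestInvariants:
    def test_symmetry(self, rng):
        g = Grid((12, 12, 12), (1.0, 2.0, 1.5))
        m1 = StructureMask(random_blob_mask(g.shape, rng), g)
        m2 = StructureMask(random_blob_mask(g.shape, rng), g)
        a, b = extract_surface(m1).points, extract_surface(m2).points
        assert hausdorff(a, b) == hausdorff(b, a)
        assert mean_distance_to_agreement(a, b) == mean_distance_to_agreement(b, a)
        assert dice(m1, m2) == dice(m2, m1)
        assert jaccard(m1, m2) == jaccard(m2, m1)

    def test_jaccard_dice_identity_per_pair(self, rng):
        g = Grid((12, 12, 12), (1.0, 1.0, 1.0))
        for _ in range(10):
            m1 = StructureMask(random_blob_mask(g.shape, rng), g)
            m2 = StructureMask(random_blob_mask(g.shape, rng), g)
            d = dice(m1, m2)
            assert jaccard(m1, m2) == pytest.approx(d / (2.0 - d), abs=1e-12)

    def test_hd_nondecreasing_when_far_voxel_added(self, rng):
        g = Grid((20, 10, 10), (1.0, 1.0, 1.0))
        m1 = np.zeros(g.shape, bool)
        m1[2:5, 2:5, 2:5] = True
        m2 = m1.copy()
        s1 = extract_surface(StructureMask(m1, g))
        s2 = extract_surface(StructureMask(m2, g))
        base = hausdorff(s1, s2)
        m2[19, 9, 9] = True
        s2b = extract_surface(StructureMask(m2, g))
        assert hausdorff(s1, s2b) >= base

    def test_hd_at_least_mda(self, rng):
        g = Grid((12, 12, 12), (1.0, 1.0, 1.0))
        m1 = StructureMask(random_blob_mask(g.shape, rng), g)
        m2 = StructureMask(random_blob_mask(g.shape, rng), g)
        a, b = extract_surface(m1).points, extract_surface(m2).points
        assert hausdorff(a, b) >= mean_distance_to_agreement(a, b)


class TestEvaluatePair:
    def test_identical_masks_are_perfect(self, rng):
        g = Grid((10, 10, 10), (2.0, 2.0, 3.0))
        m = StructureMask(random_blob_mask(g.shape, rng), g, organ="bladder")
        rec = evaluate_pair(m, m, patient_id="P1", fraction=3, algorithm="nib")
        assert (rec.hd_mm, rec.mda_mm, rec.dsc, rec.jaccard) == (0.0, 0.0, 1.0, 1.0)

    def test_composition_matches_individual_metrics(self, rng):
        g = Grid((12, 12, 12), (1.0, 1.0, 2.0))
        m1 = StructureMask(random_blob_mask(g.shape, rng), g, organ="rectum")
        m2 = StructureMask(random_blob_mask(g.shape, rng), g, organ="rectum")
        rec = evaluate_pair(m1, m2)
        a, b = extract_surface(m1), extract_surface(m2)
        assert rec.hd_mm == hausdorff(a, b)
        assert rec.mda_mm == mean_distance_to_agreement(a, b)
        assert rec.dsc == dice(m1, m2)
        assert rec.jaccard == jaccard(m1, m2)
        assert rec.jaccard <= rec.dsc
        assert rec.hd_mm >= rec.mda_mm

    def test_errors(self):
        g = Grid((6, 6, 6), (1.0, 1.0, 1.0))
        g2 = Grid((6, 6, 6), (2.0, 1.0, 1.0))
        empty = StructureMask(np.zeros(g.shape, bool), g)
        full = StructureMask(np.ones(g.shape, bool), g)
        other = StructureMask(np.ones(g2.shape, bool), g2)
        with pytest.raises(UndefinedMetricError):
            dice(empty, empty)
        with pytest.raises(GridMismatchError):
            dice(full, other)
        with pytest.raises(EmptyStructureError):
            evaluate_pair(full, empty)
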