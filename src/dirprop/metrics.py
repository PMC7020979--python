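"""Contour similarity metrics: Hausdorff, mean distance to agreement, Dice, Jaccard.

Distances are Euclidean distances in millimetres between surface-voxel
centers (anisotropic spacing honoured); overlap ratios are voxel-count
ratios on a shared grid.

* HD(A, B)  = max( max_a d(a, B), max_b d(b, A) )           [mm]
* MDA(A, B) = mean over the pooled directed distances
              {d(a, B) : a in A} ∪ {d(b, A) : b in B}       [mm]
* DSC       = 2|V1 ∩ V2| / (|V1| + |V2|)
* JI        = |V1 ∩ V2| / |V1 ∪ V2|

The fast path uses a k-d tree for nearest-neighbour queries; an O(N^2)
brute-force twin of each distance metric lives in the test suite as the
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, GridMismatchError, UndefinedMetricError
from .image_model import StructureMask, SurfacePointSet, extract_surface

ALGORITHMS = ("rigid_only", "dir_profile", "nib", "shadowed_nib")


@dataclass
class MetricRecord:
    """One evaluated contour comparison for a (patient, fraction, organ, algorithm)."""

    patient_id: str
    fraction: int
    modality: str
    organ: str
    algorithm: str
    hd_mm: float
    mda_mm: float
    dsc: float
    jaccard: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0 and 0.0 <= self.jaccard <= 1.0):
            raise ValueError("overlap ratios must lie in [0, 1]")
        if self.hd_mm < 0 or self.mda_mm < 0:
            raise ValueError("distances must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


def _as_points(s: SurfacePointSet | np.ndarray, name: str) -> np.ndarray:
    pts = s.points if isinstance(s, SurfacePointSet) else np.asarray(s, dtype=float)
    pts = pts.reshape(-1, 3)
    if pts.shape[0] == 0:
        raise EmptyStructureError(f"point set {name} is empty")
    return pts


def directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """d(a, B) for every a in A: nearest-neighbour distances in mm."""
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return np.asarray(d, dtype=float)


def hausdorff(a: SurfacePointSet | np.ndarray, b: SurfacePointSet | np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets, in mm."""
    pa, pb = _as_points(a, "A"), _as_points(b, "B")
    return float(max(directed_distances(pa, pb).max(), directed_distances(pb, pa).max()))


def mean_distance_to_agreement(
    a: SurfacePointSet | np.ndarray, b: SurfacePointSet | np.ndarray
) -> float:
    """Symmetric mean surface distance: mean of the pooled directed distances, mm."""
    pa, pb = _as_points(a, "A"), _as_points(b, "B")
    pooled = np.concatenate([directed_distances(pa, pb), directed_distances(pb, pa)])
    return float(pooled.mean())


def directed_mean_distances(
    a: SurfacePointSet | np.ndarray, b: SurfacePointSet | np.ndarray
) -> tuple[float, float]:
    """One-sided mean surface distances (A→B, B→A), for sensitivity checks."""
    pa, pb = _as_points(a, "A"), _as_points(b, "B")
    return (
        float(directed_distances(pa, pb).mean()),
        float(directed_distances(pb, pa).mean()),
    )


def _check_pair(v1: StructureMask, v2: StructureMask) -> None:
    if v1.grid != v2.grid:
        raise GridMismatchError("masks must share a grid")
    if v1.is_empty() and v2.is_empty():
        raise UndefinedMetricError("overlap metrics undefined for two empty masks")


def dice(v1: StructureMask, v2: StructureMask) -> float:
    """Dice similarity coefficient 2|V1∩V2| / (|V1|+|V2|)."""
    _check_pair(v1, v2)
    inter = int(np.count_nonzero(v1.mask & v2.mask))
    return 2.0 * inter / (v1.voxel_count + v2.voxel_count)


def jaccard(v1: StructureMask, v2: StructureMask) -> float:
    """Jaccard index |V1∩V2| / |V1∪V2|."""
    _check_pair(v1, v2)
    inter = int(np.count_nonzero(v1.mask & v2.mask))
    union = int(np.count_nonzero(v1.mask | v2.mask))
    return inter / union


def evaluate_pair(
    manual: StructureMask,
    propagated: StructureMask,
    patient_id: str = "",
    fraction: int = 0,
    modality: str = "CTOR",
    algorithm: str = "nib",
) -> MetricRecord:
    """Compute all four similarity metrics for a manual/propagated mask pair."""
    if manual.is_empty() or propagated.is_empty():
        raise EmptyStructureError("both masks must be non-empty")
    sa = extract_surface(manual)
    sb = extract_surface(propagated)
    return MetricRecord(
        patient_id=patient_id,
        fraction=fraction,
        modality=modality,
        organ=manual.organ,
        algorithm=algorithm,
        hd_mm=hausdorff(sa, sb),
        mda_mm=mean_distance_to_agreement(sa, sb),
        dsc=dice(manual, propagated),
        jaccard=jaccard(manual, propagated),
    )
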