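"""Synthetic pelvic phantom: planning CT, per-fraction images and ground truth.

The phantom emulates the structure of a fractionated prostate-radiotherapy
study: a planning CT of a pelvis (soft tissue, bladder, rectum, pelvic bone),
and per-fraction guidance images in which

* bladder and rectum change volume by a per-fraction *filling factor*
  (radial scaling about the organ, blended smoothly to zero beyond an
  influence shell so bone stays rigid — the deformation is analytic and
  invertible for the magnitudes used),
* the whole patient undergoes a small rigid setup offset, and
* the image takes either a CT-on-rails-like appearance (high soft-tissue
  contrast) or a CBCT-like appearance (contrast compression via gain/offset,
  extra noise, and a smooth multiplicative bias field).

Every fraction carries a :class:`GroundTruth` with the exact pull-back
deformation (same convention as :class:`~dirprop.transforms.DeformationField`)
and the true organ masks, so registration and propagation can be scored
against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from scipy import ndimage

from .errors import GeometryError
from .image_model import (
    Grid,
    ImageVolume,
    ManifestRow,
    StructureMask,
    StudyManifest,
    write_mask,
    write_volume,
)
from .transforms import DeformationField, RigidTransform

SCHEDULES = ("daily", "first5_then_weekly")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CBCTModel:
    """Appearance degradation applied to CBCT-modality fractions."""

    gain: float = 0.8
    offset: float = -30.0
    noise_sd: float = 25.0
    bias_amplitude: float = 0.08
    bias_knots: tuple[int, int, int] = (4, 4, 3)


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of the synthetic study. Defaults give a small pelvic phantom.

    Distances in mm, intensities in HU. ``seed`` makes generation fully
    reproducible.
    """

    shape: tuple[int, int, int] = (64, 64, 40)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)

    # tissue intensities (HU) and CT noise
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_bladder: float = 10.0
    hu_rectum: float = -80.0
    hu_bone: float = 700.0
    noise_sd: float = 12.0
    texture_amplitude: float = 25.0
    edge_smoothing_mm: float = 2.0

    # anatomy (fractions of the field of view where sensible)
    bladder_center_frac: tuple[float, float, float] = (0.5, 0.38, 0.56)
    bladder_semi_axes_mm: tuple[float, float, float] = (20.0, 17.0, 15.0)
    rectum_center_y_frac: float = 0.70
    rectum_radius_mm: float = 8.0
    rectum_wiggle_mm: float = 6.0
    influence_ratio: float = 1.8  # deformation blends to zero at m = ratio

    # per-fraction variation
    bladder_fill_sigma: float = 0.25  # lognormal sigma of the filling factor
    rectum_fill_sigma: float = 0.15
    setup_translation_sd_mm: float = 2.0
    setup_rotation_sd_deg: float = 0.8

    cbct_model: CBCTModel = field(default_factory=CBCTModel)
    schedule: str = "daily"
    n_fractions: int = 23
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(n <= 0 for n in self.shape):
            raise ValueError("grid shape and spacing must be positive")
        if self.schedule not in SCHEDULES:
            raise ValueError(f"schedule must be one of {SCHEDULES}")
        if self.influence_ratio <= 1.0:
            raise ValueError("influence_ratio must exceed 1")

    @property
    def grid(self) -> Grid:
        return Grid(shape=self.shape, spacing=self.spacing)

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    @classmethod
    def extreme_fill(cls, **overrides) -> "PhantomConfig":
        """Stress preset: large bladder-filling swings (the discussed failure mode)."""
        return cls(bladder_fill_sigma=0.45, rectum_fill_sigma=0.25, **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cbct = raw.pop("cbct_model", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if cbct:
            cfg = replace(cfg, cbct_model=CBCTModel(**cbct))
        return cfg


# ---------------------------------------------------------------------------
# Analytic anatomy with invertible filling deformations
# ---------------------------------------------------------------------------


def _falloff(t: np.ndarray) -> np.ndarray:
    """C1 blend weight: 1 at t=0, 0 at t>=1, zero slope at both ends."""
    t = np.clip(t, 0.0, 1.0)
    return (1.0 - t**2) ** 2


def _inverse_radial(mu: np.ndarray, s: float, m_out: float) -> np.ndarray:
    """Solve r * h(r) = mu for r, where h is the blended radial scale profile.

    h(r) = s for r <= 1, blending to 1 at r = m_out. Monotone for the
    moderate scale factors used (|s - 1| well below 1).
    """
    mu = np.asarray(mu, dtype=float)
    r = np.where(mu <= s, mu / s, mu)
    mid = (mu > s) & (mu < m_out)
    if np.any(mid):
        mu_m = mu[mid]
        lo = np.ones_like(mu_m)
        hi = np.full_like(mu_m, m_out)

        def fwd(r_: np.ndarray) -> np.ndarray:
            t = (r_ - 1.0) / (m_out - 1.0)
            return r_ * (1.0 + (s - 1.0) * _falloff(t))

        for _ in range(48):
            mid_r = 0.5 * (lo + hi)
            too_low = fwd(mid_r) < mu_m
            lo = np.where(too_low, mid_r, lo)
            hi = np.where(too_low, hi, mid_r)
        r[mid] = 0.5 * (lo + hi)
    return r


class EllipsoidOrgan:
    """Ellipsoidal organ (bladder) with radial filling deformation about its center."""

    def __init__(self, center: np.ndarray, semi_axes: np.ndarray, m_out: float):
        self.center = np.asarray(center, dtype=float)
        self.semi_axes = np.asarray(semi_axes, dtype=float)
        self.m_out = float(m_out)

    def m(self, pts: np.ndarray) -> np.ndarray:
        rel = (pts - self.center) / self.semi_axes
        return np.linalg.norm(rel, axis=-1)

    def inside(self, pts: np.ndarray, fill: float = 1.0) -> np.ndarray:
        s = fill ** (1.0 / 3.0)
        return self.m(pts) <= s

    def scale_factor(self, fill: float) -> float:
        """Linear scale s: organ volume scales by s^3 = fill."""
        return fill ** (1.0 / 3.0)

    def pull_back(self, pts: np.ndarray, fill: float) -> np.ndarray:
        """Map fraction-space points back to planning space (inverse deformation)."""
        s = self.scale_factor(fill)
        if s == 1.0:
            return pts
        mu = self.m(pts)
        r = _inverse_radial(mu, s, self.m_out)
        ratio = np.where(mu > 0, r / np.maximum(mu, 1e-12), 1.0)
        return self.center + (pts - self.center) * ratio[..., None]

    def push_forward(self, pts: np.ndarray, fill: float) -> np.ndarray:
        s = self.scale_factor(fill)
        if s == 1.0:
            return pts
        m = self.m(pts)
        t = (m - 1.0) / (self.m_out - 1.0)
        h = np.where(m <= 1.0, s, 1.0 + (s - 1.0) * _falloff(t))
        return self.center + (pts - self.center) * h[..., None]


class TubeOrgan:
    """Curved tube along z (rectum) with in-plane radial filling deformation."""

    def __init__(
        self,
        x0: float,
        y0: float,
        radius: float,
        wiggle: float,
        z_extent: float,
        m_out: float,
    ):
        self.x0, self.y0 = float(x0), float(y0)
        self.radius = float(radius)
        self.wiggle = float(wiggle)
        self.z_extent = float(z_extent)
        self.m_out = float(m_out)

    def centerline_x(self, z: np.ndarray) -> np.ndarray:
        return self.x0 + self.wiggle * np.sin(2.0 * np.pi * z / (1.3 * self.z_extent))

    def m(self, pts: np.ndarray) -> np.ndarray:
        cx = self.centerline_x(pts[..., 2])
        return (
            np.sqrt((pts[..., 0] - cx) ** 2 + (pts[..., 1] - self.y0) ** 2)
            / self.radius
        )

    def inside(self, pts: np.ndarray, fill: float = 1.0) -> np.ndarray:
        return self.m(pts) <= self.scale_factor(fill)

    def scale_factor(self, fill: float) -> float:
        """In-plane scale s: tube cross-section area scales by s^2 = fill."""
        return fill**0.5

    def pull_back(self, pts: np.ndarray, fill: float) -> np.ndarray:
        s = self.scale_factor(fill)
        if s == 1.0:
            return pts
        mu = self.m(pts)
        r = _inverse_radial(mu, s, self.m_out)
        ratio = np.where(mu > 0, r / np.maximum(mu, 1e-12), 1.0)
        out = pts.copy()
        cx = self.centerline_x(pts[..., 2])
        out[..., 0] = cx + (pts[..., 0] - cx) * ratio
        out[..., 1] = self.y0 + (pts[..., 1] - self.y0) * ratio
        return out

    def push_forward(self, pts: np.ndarray, fill: float) -> np.ndarray:
        s = self.scale_factor(fill)
        if s == 1.0:
            return pts
        m = self.m(pts)
        t = (m - 1.0) / (self.m_out - 1.0)
        h = np.where(m <= 1.0, s, 1.0 + (s - 1.0) * _falloff(t))
        out = pts.copy()
        cx = self.centerline_x(pts[..., 2])
        out[..., 0] = cx + (pts[..., 0] - cx) * h
        out[..., 1] = self.y0 + (pts[..., 1] - self.y0) * h
        return out


@dataclass
class Anatomy:
    """Analytic description of the phantom's tissues in world coordinates."""

    config: PhantomConfig
    bladder: EllipsoidOrgan
    rectum: TubeOrgan
    body_center: np.ndarray
    body_semi: np.ndarray
    bone_centers: tuple[tuple[float, float], ...]
    bone_radius: float
    sacrum_box: tuple[tuple[float, float], tuple[float, float]]

    def in_body(self, pts: np.ndarray) -> np.ndarray:
        # slight cranio-caudal taper so the outline carries z information
        z_ext = self.config.extent_mm[2]
        taper = 1.0 - 0.06 * (pts[..., 2] / z_ext - 0.5)
        rel = (pts[..., :2] - self.body_center[:2]) / (
            self.body_semi[:2] * taper[..., None]
        )
        return (rel**2).sum(axis=-1) <= 1.0

    def in_bone(self, pts: np.ndarray) -> np.ndarray:
        # bone radii vary along z (femoral-head-like bulges) so the rigid
        # anatomy pins down z translation and x/y rotations
        z_ext = self.config.extent_mm[2]
        out = np.zeros(pts.shape[:-1], dtype=bool)
        for i, (bx, by) in enumerate(self.bone_centers):
            phase = 0.0 if i == 0 else np.pi / 2.0
            rad = self.bone_radius * (
                1.0 + 0.35 * np.sin(2.0 * np.pi * pts[..., 2] / z_ext + phase)
            )
            out |= (pts[..., 0] - bx) ** 2 + (pts[..., 1] - by) ** 2 <= rad**2
        (x0, x1), (y0, y1) = self.sacrum_box
        zmod = 4.0 * np.sin(2.0 * np.pi * pts[..., 2] / (0.6 * z_ext))
        out |= (
            (pts[..., 0] >= x0)
            & (pts[..., 0] <= x1)
            & (pts[..., 1] >= y0 + zmod)
            & (pts[..., 1] <= y1 + zmod)
        )
        return out

    def clean_hu(self, pts: np.ndarray, texture: Callable[[np.ndarray], np.ndarray] | None = None) -> np.ndarray:
        """Noise-free HU at arbitrary world points."""
        cfg = self.config
        hu = np.full(pts.shape[:-1], cfg.hu_air, dtype=float)
        body = self.in_body(pts)
        hu[body] = cfg.hu_soft
        if texture is not None:
            hu[body] += texture(pts[body])
        hu[body & self.bladder.inside(pts)] = cfg.hu_bladder
        hu[body & self.rectum.inside(pts)] = cfg.hu_rectum
        hu[body & self.in_bone(pts)] = cfg.hu_bone
        return hu


def build_anatomy(config: PhantomConfig) -> Anatomy:
    ext = config.extent_mm
    center = ext / 2.0
    bladder = EllipsoidOrgan(
        center=np.asarray(config.bladder_center_frac) * ext,
        semi_axes=np.asarray(config.bladder_semi_axes_mm),
        m_out=config.influence_ratio,
    )
    rectum = TubeOrgan(
        x0=center[0],
        y0=config.rectum_center_y_frac * ext[1],
        radius=config.rectum_radius_mm,
        wiggle=config.rectum_wiggle_mm,
        z_extent=ext[2],
        m_out=config.influence_ratio,
    )
    body_semi = np.array([0.46 * ext[0], 0.41 * ext[1], np.inf])
    bone_off = 0.34 * ext[0]
    anatomy = Anatomy(
        config=config,
        bladder=bladder,
        rectum=rectum,
        body_center=center,
        body_semi=body_semi,
        bone_centers=((center[0] - bone_off, center[1]), (center[0] + bone_off, center[1])),
        bone_radius=8.0,
        sacrum_box=(
            (center[0] - 18.0, center[0] + 18.0),
            (0.825 * ext[1], 0.89 * ext[1]),
        ),
    )
    _check_anatomy_fits(anatomy)
    return anatomy


def _check_anatomy_fits(anatomy: Anatomy, fill: dict[str, float] | None = None) -> None:
    cfg = anatomy.config
    ext = cfg.extent_mm
    fill = fill or {}
    s_b = anatomy.bladder.scale_factor(fill.get("bladder", 1.0))
    lo = anatomy.bladder.center - s_b * anatomy.bladder.semi_axes
    hi = anatomy.bladder.center + s_b * anatomy.bladder.semi_axes
    if np.any(lo < 0) or np.any(hi > ext):
        raise GeometryError("bladder (at requested fill) exceeds the grid extent")
    s_r = anatomy.rectum.scale_factor(fill.get("rectum", 1.0))
    r = s_r * anatomy.rectum.radius
    if (
        anatomy.rectum.y0 - r < 0
        or anatomy.rectum.y0 + r > ext[1]
        or anatomy.rectum.x0 - anatomy.rectum.wiggle - r < 0
        or anatomy.rectum.x0 + anatomy.rectum.wiggle + r > ext[0]
    ):
        raise GeometryError("rectum (at requested fill) exceeds the grid extent")


# ---------------------------------------------------------------------------
# Planning phantom
# ---------------------------------------------------------------------------


def _smooth_random_field(
    shape: tuple[int, int, int], knots: tuple[int, int, int], rng: np.random.Generator
) -> np.ndarray:
    """Smooth zero-mean random field on a voxel grid via spline upsampling."""
    coarse = rng.standard_normal(knots)
    zoom = [n / k for n, k in zip(shape, knots)]
    f = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    return f[: shape[0], : shape[1], : shape[2]]


@dataclass
class PlanningPhantom:
    """Planning CT with organ masks plus everything needed to spawn fractions."""

    image: ImageVolume
    masks: dict[str, StructureMask]
    clean_hu: np.ndarray  # noise-free HU on the planning grid
    anatomy: Anatomy
    config: PhantomConfig

    @property
    def grid(self) -> Grid:
        return self.image.grid


def _render_clean(
    anatomy: Anatomy, grid: Grid, pts: np.ndarray, texture_vol: np.ndarray | None
) -> np.ndarray:
    """Noise-free smoothed HU sampled at world points on a grid-shaped array."""
    cfg = anatomy.config
    if texture_vol is None:
        texture = None
    else:
        def texture(p: np.ndarray) -> np.ndarray:
            idx = grid.world_to_index(p)
            return ndimage.map_coordinates(
                texture_vol, idx.T, order=1, mode="nearest"
            )

    hu = anatomy.clean_hu(pts, texture=texture)
    sigma_vox = cfg.edge_smoothing_mm / grid.spacing_arr
    return ndimage.gaussian_filter(hu, sigma=sigma_vox)


def make_planning_phantom(config: PhantomConfig, rng: np.random.Generator | None = None) -> PlanningPhantom:
    """Build the planning CT and its bladder/rectum masks.

    The organ masks are disjoint by construction (bladder test wins where the
    influence shells would overlap — they do not at the default geometry).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    anatomy = build_anatomy(config)
    grid = config.grid
    pts = np.moveaxis(grid.world_coordinates(), 0, -1)

    texture_vol = config.texture_amplitude * _smooth_random_field(
        config.shape, (8, 8, 6), rng
    )

    clean = _render_clean(anatomy, grid, pts, texture_vol)
    noisy = clean + rng.normal(0.0, config.noise_sd, size=grid.shape)
    image = ImageVolume(voxels=noisy.astype(np.float32), grid=grid, modality="PCT")

    bladder = StructureMask(anatomy.bladder.inside(pts), grid, organ="bladder")
    rectum_mask = anatomy.rectum.inside(pts) & ~bladder.mask & anatomy.in_body(pts)
    rectum = StructureMask(rectum_mask, grid, organ="rectum")
    if bladder.is_empty() or rectum.is_empty():
        raise GeometryError("an organ mask is empty at this grid resolution")
    return PlanningPhantom(
        image=image,
        masks={"bladder": bladder, "rectum": rectum},
        clean_hu=clean,
        anatomy=anatomy,
        config=config,
    )


# ---------------------------------------------------------------------------
# Fractions
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Exact generative answer for one fraction."""

    setup: RigidTransform  # maps planning world coords to fraction world coords
    dvf_pullback: DeformationField  # total pull-back (incl. rigid) on fraction grid
    masks: dict[str, StructureMask]  # true organ masks on the fraction grid
    filling: dict[str, float]
    fraction: int
    modality: str

    def pull_back_points(self, pts: np.ndarray) -> np.ndarray:
        """Exact planning-space location of fraction-space points (analytic)."""
        raise NotImplementedError  # replaced per-instance in make_fraction


def sample_filling(config: PhantomConfig, rng: np.random.Generator) -> dict[str, float]:
    return {
        "bladder": float(np.exp(rng.normal(0.0, config.bladder_fill_sigma))),
        "rectum": float(np.exp(rng.normal(0.0, config.rectum_fill_sigma))),
    }


def sample_setup(config: PhantomConfig, rng: np.random.Generator, grid: Grid) -> RigidTransform:
    t = rng.normal(0.0, config.setup_translation_sd_mm, size=3)
    r = rng.normal(0.0, config.setup_rotation_sd_deg, size=3)
    return RigidTransform(
        rotation_deg=tuple(np.clip(r, -3.0, 3.0)),
        translation_mm=tuple(np.clip(t, -8.0, 8.0)),
        center_mm=tuple(grid.center_world),
    )


def make_fraction(
    planning: PlanningPhantom,
    fraction_index: int,
    rng: np.random.Generator,
    modality: str = "CTOR",
    filling: dict[str, float] | None = None,
    setup: RigidTransform | None = None,
    noise_sd: float | None = None,
) -> tuple[ImageVolume, GroundTruth]:
    """Generate one fractional guidance image plus its ground truth.

    The generative (forward) model takes planning anatomy, applies the
    organ-filling deformation, then the rigid setup offset, then the modality
    appearance. The image is rendered by pulling each fraction voxel back to
    planning space, so the stored pull-back map is exact by construction.
    """
    cfg = planning.config
    anatomy = planning.anatomy
    grid = planning.grid
    if filling is None:
        filling = sample_filling(cfg, rng)
    if setup is None:
        setup = sample_setup(cfg, rng, grid)
    _check_anatomy_fits(anatomy, filling)

    def pull_back(pts: np.ndarray) -> np.ndarray:
        p = setup.inverse().apply(pts)
        p = anatomy.bladder.pull_back(p, filling["bladder"])
        p = anatomy.rectum.pull_back(p, filling["rectum"])
        return p

    pts = np.moveaxis(grid.world_coordinates(), 0, -1)
    flat = pts.reshape(-1, 3)
    back = pull_back(flat)

    # render the geometry by sampling the noise-free planning HU
    idx = grid.world_to_index(back)
    # edge replication: content leaving the volume is clamped to the edge
    # slice, emulating a longer body rather than creating artificial air slabs
    clean_frac = ndimage.map_coordinates(
        planning.clean_hu, idx.T, order=1, mode="nearest"
    ).reshape(grid.shape)

    if modality == "CBCT":
        cm = cfg.cbct_model
        bias = 1.0 + cm.bias_amplitude * _smooth_random_field(grid.shape, cm.bias_knots, rng)
        # bias multiplies attenuation (HU + 1000), then global gain/offset
        hu = (clean_frac + 1000.0) * bias - 1000.0
        hu = cm.gain * hu + cm.offset
        hu = hu + rng.normal(0.0, cm.noise_sd, size=grid.shape)
    elif modality == "CTOR":
        sd = cfg.noise_sd if noise_sd is None else noise_sd
        hu = clean_frac + (rng.normal(0.0, sd, size=grid.shape) if sd > 0 else 0.0)
    else:
        raise ValueError(f"fraction modality must be CTOR or CBCT, got {modality!r}")

    image = ImageVolume(voxels=hu.astype(np.float32), grid=grid, modality=modality)

    # true masks: planning voxel masks warped by the exact pull-back map
    # (linear interpolation, threshold 0.5 — the voxelization convention used
    # throughout the package)
    back_grid = back.reshape(grid.shape + (3,))
    masks = {}
    for organ, pmask in planning.masks.items():
        warped = ndimage.map_coordinates(
            pmask.mask.astype(np.float32), idx.T, order=1, mode="constant"
        ).reshape(grid.shape)
        masks[organ] = StructureMask(warped >= 0.5, grid, organ=organ)
    dvf = DeformationField(back_grid - pts, grid)
    gt = GroundTruth(
        setup=setup,
        dvf_pullback=dvf,
        masks=masks,
        filling=dict(filling),
        fraction=fraction_index,
        modality=modality,
    )
    gt.pull_back_points = pull_back  # type: ignore[method-assign]
    return image, gt


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------


def manual_fractions(schedule: str, n_fractions: int) -> list[int]:
    """Fractions carrying manual contours: all of them, or 1-5 then every 5th."""
    if schedule == "daily":
        return list(range(1, n_fractions + 1))
    if schedule == "first5_then_weekly":
        out = list(range(1, min(5, n_fractions) + 1))
        out += [f for f in range(10, n_fractions + 1, 5)]
        return out
    raise ValueError(f"unknown schedule {schedule!r}")


def make_study(
    config: PhantomConfig,
    n_patients_ctor: int,
    n_patients_cbct: int,
    out_dir: str | Path,
) -> StudyManifest:
    """Generate a full study tree (NIfTI volumes + manifest CSV) on disk.

    Within each modality group, the first half of the patients follow a daily
    manual-contouring schedule and the rest follow first-five-then-weekly,
    mirroring a mixed-schedule cohort. Deterministic given ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows: list[ManifestRow] = []
    specs = [("CTOR", i, n_patients_ctor) for i in range(n_patients_ctor)]
    specs += [("CBCT", i, n_patients_cbct) for i in range(n_patients_cbct)]
    seeds = np.random.SeedSequence(config.seed).spawn(len(specs))

    for pidx, ((modality, gi, gn), seed) in enumerate(zip(specs, seeds)):
        pid = f"P{pidx + 1:02d}"
        schedule = "daily" if gi < (gn + 1) // 2 else "first5_then_weekly"
        rng = np.random.default_rng(seed)
        pdir = out / pid
        pdir.mkdir(exist_ok=True)

        planning = make_planning_phantom(config, rng)
        img_path = pdir / "planning.nii.gz"
        write_volume(planning.image, img_path)
        bpath = pdir / "planning_bladder.nii.gz"
        rpath = pdir / "planning_rectum.nii.gz"
        write_mask(planning.masks["bladder"], bpath)
        write_mask(planning.masks["rectum"], rpath)
        rows.append(
            ManifestRow(pid, 0, "PCT", "reference", str(img_path), str(bpath), str(rpath))
        )

        with_masks = set(manual_fractions(schedule, config.n_fractions))
        for f in range(1, config.n_fractions + 1):
            image, gt = make_fraction(planning, f, rng, modality=modality)
            fpath = pdir / f"fraction_{f:02d}.nii.gz"
            write_volume(image, fpath)
            bm = rm = ""
            if f in with_masks:
                bm = str(pdir / f"fraction_{f:02d}_bladder.nii.gz")
                rm = str(pdir / f"fraction_{f:02d}_rectum.nii.gz")
                write_mask(gt.masks["bladder"], bm)
                write_mask(gt.masks["rectum"], rm)
            rows.append(ManifestRow(pid, f, modality, "fraction", str(fpath), bm, rm))

    manifest = StudyManifest(rows=rows)
    manifest.save(out / "manifest.csv")
    return manifest
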