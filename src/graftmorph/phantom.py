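"""Synthetic CT phantom pairs with complete ground truth.

No patient imaging is distributable, so validation runs on schematic
digital phantoms: a scapula-like body (two overlapping ellipsoids — a thin
blade and a glenoid boss) carrying a capsule-shaped coracoid protrusion.
The follow-up scan is generated by virtually performing the operation with
known parameters: the coracoid is osteotomized at a known plane, the graft
segment is placed on the anterior glenoid by a known rigid pose, two
screws (4.5 mm shaft diameter, wider head sitting proud of the graft
surface) are inserted at high intensity, a known fraction of graft voxels
is resorbed with a spatial gradient, the whole scene is moved by a known
inter-scan rigid transform, and Gaussian noise is added.

All ground-truth volumes are exact voxel counts recorded *before* noise.
The geometry is deliberately schematic: acceptance properties need known
volumes, not anatomical realism.

Canonical pre-operative frame: +z superior, +x anterior (superficial),
+y lateral (so medial is -y). Default intensities: background 0 HU, bone
700 HU, metal 3000 HU, noise sigma 20 HU; default spacing 0.75 mm
(matching the 0.75 mm slice thickness of the validation study's scans).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError
from .graft_morphometry import AxisFrame, OsteotomyPlane, ScrewModel
from .io_formats import BinaryMask, CTVolume
from .registration import RigidTransform

log = logging.getLogger(__name__)

# --- fixed schematic anatomy (mm, canonical pre-op frame) -------------------
BLADE_CENTER = np.array([-20.0, 0.0, -15.0])
BLADE_SEMI = np.array([7.0, 32.0, 38.0])
BOSS_CENTER = np.array([-8.0, 0.0, 0.0])
BOSS_SEMI = np.array([10.0, 11.0, 14.0])
# scapular-spine-like ridge and inferior-angle knob: asymmetric features that
# anchor the rotational degrees of freedom of surface registration
SPINE_CENTER = np.array([-26.0, -8.0, 8.0])
SPINE_SEMI = np.array([5.0, 28.0, 6.0])
KNOB_CENTER = np.array([-20.0, 10.0, -48.0])
KNOB_SEMI = np.array([6.0, 7.0, 9.0])
CORACOID_BASE = np.array([-6.0, 3.0, 10.0])
CORACOID_DIR = np.array([0.755, 0.352, 0.553]) / np.linalg.norm([0.755, 0.352, 0.553])
GRAFT_CUT_TARGET = np.array([8.5, 0.0, -9.0])   # where the cut face lands on the glenoid
GRAFT_AXIS_TARGET = np.array([0.0, 0.0, 1.0])   # graft long axis after placement
SCREW_Z = (5.5, -5.5)                            # superior and inferior screw heights
SCREW_TIP_X = -10.0
SCREW_SHAFT_RADIUS = 2.25                        # 4.5 mm screws
SCREW_HEAD_RADIUS = 4.0
SCREW_HEAD_LENGTH = 3.0
GLENOID_LANDMARK = np.array([2.0, 0.0, 0.0])     # anterior glenoid rim, pre-op frame

GRADIENT_AXES = {
    "superior": np.array([0.0, 0.0, 1.0]),
    "inferior": np.array([0.0, 0.0, -1.0]),
    "superficial": np.array([1.0, 0.0, 0.0]),
    "medial": np.array([0.0, -1.0, 0.0]),
    "uniform": None,
}


@dataclass
class PhantomSpec:
    """All parameters of one synthetic pre-op / follow-up pair."""

    voxel_spacing: float = 0.75
    bone_hu: float = 700.0
    metal_hu: float = 3000.0
    background_hu: float = 0.0
    coracoid_length: float = 26.0
    coracoid_radius: float = 7.0
    osteotomy_offset: float = 6.0   # cut distance from the coracoid base, mm
    interscan_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    resorption_fraction: float = 0.0
    resorption_gradient: str = "superior"
    gradient_strength: float = 24.0  # weighting of the spared vs resorbed end
    noise_sigma: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.resorption_fraction <= 1.0):
            raise ConfigError("resorption_fraction must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.resorption_gradient not in GRADIENT_AXES:
            raise ConfigError(
                f"unknown gradient {self.resorption_gradient!r}; "
                f"choose from {sorted(GRADIENT_AXES)}"
            )
        if self.osteotomy_offset + self.coracoid_radius >= self.coracoid_length:
            raise ConfigError("osteotomy_offset leaves no cylindrical graft segment")

    # -- derived geometry (canonical frame) --------------------------------
    @property
    def osteotomy_plane(self) -> OsteotomyPlane:
        return OsteotomyPlane(
            CORACOID_BASE + self.osteotomy_offset * CORACOID_DIR, -CORACOID_DIR
        )

    @property
    def graft_length(self) -> float:
        return self.coracoid_length - self.osteotomy_offset

    @property
    def analytic_graft_volume(self) -> float:
        """pi r^2 h + (2/3) pi r^3 for the cut capsule segment."""
        r = self.coracoid_radius
        h = self.graft_length - r
        return float(np.pi * r**2 * h + (2.0 / 3.0) * np.pi * r**3)

    @property
    def graft_pose(self) -> RigidTransform:
        """Rigid map taking the cut coracoid segment onto the glenoid."""
        u = CORACOID_DIR
        v = GRAFT_AXIS_TARGET
        axis = np.cross(u, v)
        s = np.linalg.norm(axis)
        c = float(u @ v)
        if s < 1e-12:
            R = np.eye(3) if c > 0 else -np.eye(3)
        else:
            from ._mesh import rotation_about_axis
            R = rotation_about_axis(axis, np.arctan2(s, c))
        cut_point = CORACOID_BASE + self.osteotomy_offset * CORACOID_DIR
        t = GRAFT_CUT_TARGET - R @ cut_point
        return RigidTransform(R, t)


def random_interscan_transform(seed: int, max_rotation_deg: float = 30.0,
                               max_translation_mm: float = 20.0) -> RigidTransform:
    """A seeded patient-repositioning transform within the stated bounds."""
    from ._mesh import rotation_about_axis

    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    angle = np.radians(rng.uniform(0.2 * max_rotation_deg, max_rotation_deg))
    R = rotation_about_axis(axis, angle)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(R, t)


@dataclass
class PhantomGroundTruth:
    """Exact bookkeeping recorded while building the follow-up scene."""

    graft_volume_t0: float
    graft_volume_followup: float
    resorption_pct: float
    regional_resorbed_pct: dict
    expected_zhu_grade: int
    per_screw_grades: tuple
    interscan_transform: RigidTransform
    osteotomy_plane: OsteotomyPlane
    graft_pose: RigidTransform
    screws: list
    axes_followup: AxisFrame
    glenoid_landmark: np.ndarray
    analytic_graft_volume: float
    coracoid_tip_preop: np.ndarray


# ---------------------------------------------------------------------------
# implicit primitives
# ---------------------------------------------------------------------------

def _ellipsoid(coords, center, semi, rotation=None):
    x = coords - center
    if rotation is not None:
        x = x @ rotation  # == R.T applied to rows
    return ((x / semi) ** 2).sum(axis=1) <= 1.0


def _capsule(coords, p0, p1, radius):
    ab = p1 - p0
    t = np.clip((coords - p0) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(coords - p0 - t[:, None] * ab, axis=1) <= radius


def _cylinder(coords, p0, p1, radius):
    ab = p1 - p0
    L2 = ab @ ab
    t = (coords - p0) @ ab / L2
    radial = np.linalg.norm(coords - p0 - t[:, None] * ab, axis=1)
    return (radial <= radius) & (t >= 0.0) & (t <= 1.0)


def _ball(coords, center, radius):
    return np.linalg.norm(coords - center, axis=1) <= radius


def _make_grid(points: np.ndarray, spacing: float, margin: float = 8.0):
    lo = points.min(axis=0) - margin
    hi = points.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return lo, shape


def _grid_coords(origin, spacing, shape):
    idx = np.indices(tuple(shape)).reshape(3, -1).T
    return origin + idx * spacing


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _preop_masks(spec: PhantomSpec):
    """Pre-op bone mask and grid metadata, canonical frame."""
    tip = CORACOID_BASE + spec.coracoid_length * CORACOID_DIR
    anchors = np.vstack([
        BLADE_CENTER - BLADE_SEMI, BLADE_CENTER + BLADE_SEMI,
        BOSS_CENTER - BOSS_SEMI, BOSS_CENTER + BOSS_SEMI,
        SPINE_CENTER - SPINE_SEMI, SPINE_CENTER + SPINE_SEMI,
        KNOB_CENTER - KNOB_SEMI, KNOB_CENTER + KNOB_SEMI,
        tip + spec.coracoid_radius, tip - spec.coracoid_radius,
    ])
    origin, shape = _make_grid(anchors, spec.voxel_spacing)
    coords = _grid_coords(origin, spec.voxel_spacing, shape)
    cap_end = CORACOID_BASE + (spec.coracoid_length - spec.coracoid_radius) * CORACOID_DIR
    bone = (
        _ellipsoid(coords, BLADE_CENTER, BLADE_SEMI)
        | _ellipsoid(coords, BOSS_CENTER, BOSS_SEMI)
        | _ellipsoid(coords, SPINE_CENTER, SPINE_SEMI)
        | _ellipsoid(coords, KNOB_CENTER, KNOB_SEMI)
        | _capsule(coords, CORACOID_BASE, cap_end, spec.coracoid_radius)
    )
    return bone.reshape(tuple(shape)), origin, shape


def _followup_scene(spec: PhantomSpec):
    """Follow-up masks (native bone, graft region, screws) in the moved frame."""
    T = spec.interscan_transform
    R = T.rotation

    pose = spec.graft_pose
    g0 = T.apply(GRAFT_CUT_TARGET)                      # cut face centre
    gdir = R @ GRAFT_AXIS_TARGET
    cyl_len = spec.graft_length - spec.coracoid_radius  # flat face to hemisphere centre
    g1 = g0 + cyl_len * gdir

    cut_plane_pt = T.apply(CORACOID_BASE + spec.osteotomy_offset * CORACOID_DIR)
    cora_base = T.apply(CORACOID_BASE)

    # screws pass through the placed graft into the glenoid, along -x; the
    # head sits proud of the graft surface (base flush with it)
    screws = []
    surface_x = GRAFT_CUT_TARGET[0] + spec.coracoid_radius
    for z in SCREW_Z:
        head_base = T.apply(np.array([surface_x, 0.0, z]))
        tip = T.apply(np.array([SCREW_TIP_X, 0.0, z]))
        head_top = T.apply(np.array([surface_x + SCREW_HEAD_LENGTH, 0.0, z]))
        screws.append((tip, head_base, head_top))

    anchors = np.vstack(
        [T.apply(p) for p in (
            BLADE_CENTER - BLADE_SEMI, BLADE_CENTER + BLADE_SEMI,
            BLADE_CENTER - BLADE_SEMI * [1, -1, -1], BLADE_CENTER + BLADE_SEMI * [1, -1, -1],
            BLADE_CENTER - BLADE_SEMI * [-1, 1, -1], BLADE_CENTER + BLADE_SEMI * [-1, 1, -1],
            BLADE_CENTER - BLADE_SEMI * [-1, -1, 1], BLADE_CENTER + BLADE_SEMI * [-1, -1, 1],
            BOSS_CENTER - BOSS_SEMI, BOSS_CENTER + BOSS_SEMI,
            SPINE_CENTER - SPINE_SEMI, SPINE_CENTER + SPINE_SEMI,
            SPINE_CENTER - SPINE_SEMI * [1, -1, -1], SPINE_CENTER + SPINE_SEMI * [1, -1, -1],
            KNOB_CENTER - KNOB_SEMI, KNOB_CENTER + KNOB_SEMI,
            KNOB_CENTER - KNOB_SEMI * [1, -1, -1], KNOB_CENTER + KNOB_SEMI * [1, -1, -1],
        )]
        + [g0 - spec.coracoid_radius, g0 + spec.coracoid_radius,
           g1 + gdir * spec.coracoid_radius + spec.coracoid_radius,
           g1 + gdir * spec.coracoid_radius - spec.coracoid_radius]
        + [s[0] for s in screws] + [s[2] + SCREW_HEAD_RADIUS for s in screws]
        + [s[2] - SCREW_HEAD_RADIUS for s in screws]
    )
    origin, shape = _make_grid(anchors, spec.voxel_spacing)
    coords = _grid_coords(origin, spec.voxel_spacing, shape)

    native = (
        _ellipsoid(coords, T.apply(BLADE_CENTER), BLADE_SEMI, rotation=R)
        | _ellipsoid(coords, T.apply(BOSS_CENTER), BOSS_SEMI, rotation=R)
        | _ellipsoid(coords, T.apply(SPINE_CENTER), SPINE_SEMI, rotation=R)
        | _ellipsoid(coords, T.apply(KNOB_CENTER), KNOB_SEMI, rotation=R)
        | _cylinder(coords, cora_base, cut_plane_pt, spec.coracoid_radius)
    )
    graft = (
        _cylinder(coords, g0, g1, spec.coracoid_radius)
        | _ball(coords, g1, spec.coracoid_radius)
    ) & ~native

    metal = np.zeros(len(coords), dtype=bool)
    screw_models = []
    for tip, head_base, head_top in screws:
        metal |= _cylinder(coords, tip, head_base, SCREW_SHAFT_RADIUS)
        metal |= _cylinder(coords, head_base, head_top, SCREW_HEAD_RADIUS)
        axis = head_top - tip
        axis = axis / np.linalg.norm(axis)
        screw_models.append(ScrewModel(
            axis=axis, tip=tip,
            length=float(np.linalg.norm(head_top - tip)),
            shaft_radius=SCREW_SHAFT_RADIUS,
            head_center=0.5 * (head_base + head_top),
            head_radius=SCREW_HEAD_RADIUS,
            head_length=SCREW_HEAD_LENGTH,
        ))

    shape_t = tuple(shape)
    return (
        native.reshape(shape_t), graft.reshape(shape_t), metal.reshape(shape_t),
        origin, shape, coords, screw_models,
    )


def _erode_graft(graft: np.ndarray, coords: np.ndarray, spec: PhantomSpec,
                 gradient_dir: np.ndarray | None) -> np.ndarray:
    """Remove exactly round(fraction * N) graft voxels, surface-first,
    preferring the gradient end. Deterministic; removal sets are nested in
    the fraction, so truth volume is strictly monotone."""
    n_total = int(graft.sum())
    n_remove = int(round(spec.resorption_fraction * n_total))
    if n_remove == 0:
        return graft.copy()
    if n_remove >= n_total:
        return np.zeros_like(graft)
    edt = ndimage.distance_transform_edt(graft, sampling=(spec.voxel_spacing,) * 3)
    flat_idx = np.flatnonzero(graft.ravel())
    depth = edt.ravel()[flat_idx]
    if gradient_dir is None:
        priority = depth
    else:
        proj = coords[flat_idx] @ gradient_dir
        lo, hi = proj.min(), proj.max()
        w = (proj - lo) / max(hi - lo, 1e-9)  # 1 at the resorbed end
        priority = depth * (1.0 + spec.gradient_strength * (1.0 - w))
    order = np.argsort(priority, kind="stable")
    remove = flat_idx[order[:n_remove]]
    out = graft.copy().ravel()
    out[remove] = False
    return out.reshape(graft.shape)


def _grade_from_mask(graft_mask: np.ndarray, origin, spacing, screw: ScrewModel,
                     shaft_span: float, threshold: float = 0.95) -> int:
    """Ground-truth geometric grade from the voxel mask (bookkeeping)."""
    from .graft_morphometry import _cylinder_surface_points

    def inside(points):
        idx = np.round((points - origin) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(graft_mask.shape)), axis=1)
        vals = np.zeros(len(points), dtype=bool)
        vals[ok] = graft_mask[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        return vals

    if not graft_mask.any():
        return 3
    # proximity: any graft voxel within 2 mm of the shaft?
    idxs = np.argwhere(graft_mask)
    pts = origin + idxs * spacing
    from ._mesh import distance_point_to_segment
    gap = distance_point_to_segment(pts, screw.tip, screw.head_base).min()
    if gap - screw.shaft_radius > 2.0:
        return 3
    head_pts = _cylinder_surface_points(
        screw.head_center, screw.axis, screw.head_radius,
        0.5 * screw.head_length, n_rings=4, n_around=14)
    if inside(head_pts).mean() >= threshold:
        return 0
    end = screw.head_base - 1.5 * screw.axis
    start = screw.head_base - max(shaft_span - 1.5, 2.0) * screw.axis
    mid, half = 0.5 * (start + end), 0.5 * np.linalg.norm(end - start)
    shaft_pts = _cylinder_surface_points(
        mid, screw.axis, screw.shaft_radius, half,
        n_rings=max(6, int(2 * half)), n_around=10, include_caps=False)
    if inside(shaft_pts).mean() >= threshold:
        return 1
    return 2


def generate_phantom_pair(spec: PhantomSpec):
    """Build one pre-op / follow-up CT pair with full ground truth.

    Returns ``(preop, followup, truth)``. Truth volumes are exact voxel
    counts before noise; noise never changes the recorded truth.
    """
    rng = np.random.default_rng(spec.seed)
    sp = spec.voxel_spacing

    pre_bone, pre_origin, pre_shape = _preop_masks(spec)
    native, graft0, metal, fu_origin, fu_shape, coords, screw_models = _followup_scene(spec)

    overlap = 0  # graft is defined outside native bone by construction
    n_graft0 = int(graft0.sum())
    if n_graft0 == 0:
        raise ConfigError("graft placement produced an empty graft region")

    grad_name = spec.resorption_gradient
    gdir = GRADIENT_AXES[grad_name]
    if gdir is not None:
        gdir = spec.interscan_transform.rotation @ gdir
    graft_fu = _erode_graft(graft0, coords, spec, gdir)
    n_graft_fu = int(graft_fu.sum())

    voxel_vol = sp**3
    v0 = n_graft0 * voxel_vol
    vf = n_graft_fu * voxel_vol

    # regional bookkeeping on bounding-box half-spaces of the t0 graft
    axes_fu = AxisFrame().rotated(spec.interscan_transform.rotation)
    g_idx = np.flatnonzero(graft0.ravel())
    g_coords = coords[g_idx]
    removed = ~graft_fu.ravel()[g_idx]
    regional = {}
    for pos, neg, axv in (
        ("superior", "inferior", axes_fu.superior),
        ("medial", "lateral", axes_fu.medial),
        ("superficial", "deep", axes_fu.superficial),
    ):
        proj = g_coords @ axv
        mid = 0.5 * (proj.min() + proj.max())
        sel = proj >= mid
        regional[pos] = float(100.0 * removed[sel].mean()) if sel.any() else float("nan")
        regional[neg] = float(100.0 * removed[~sel].mean()) if (~sel).any() else float("nan")

    shaft_span = 2.0 * spec.coracoid_radius
    grades = tuple(
        _grade_from_mask(graft_fu, fu_origin, np.array([sp] * 3), s, shaft_span)
        for s in screw_models
    )

    truth = PhantomGroundTruth(
        graft_volume_t0=v0,
        graft_volume_followup=vf,
        resorption_pct=100.0 * (v0 - vf) / v0,
        regional_resorbed_pct=regional,
        expected_zhu_grade=max(grades),
        per_screw_grades=grades,
        interscan_transform=spec.interscan_transform,
        osteotomy_plane=spec.osteotomy_plane,
        graft_pose=spec.graft_pose,
        screws=screw_models,
        axes_followup=axes_fu,
        glenoid_landmark=spec.interscan_transform.apply(GLENOID_LANDMARK),
        analytic_graft_volume=spec.analytic_graft_volume,
        coracoid_tip_preop=CORACOID_BASE + spec.coracoid_length * CORACOID_DIR,
    )

    pre_data = np.full(pre_bone.shape, spec.background_hu, dtype=np.float32)
    pre_data[pre_bone] = spec.bone_hu
    fu_data = np.full(native.shape, spec.background_hu, dtype=np.float32)
    fu_data[native | graft_fu] = spec.bone_hu
    fu_data[metal] = spec.metal_hu
    if spec.noise_sigma > 0:
        pre_data += rng.normal(0.0, spec.noise_sigma, pre_data.shape).astype(np.float32)
        fu_data += rng.normal(0.0, spec.noise_sigma, fu_data.shape).astype(np.float32)

    preop = CTVolume(pre_data, (sp,) * 3, pre_origin)
    followup = CTVolume(fu_data, (sp,) * 3, fu_origin)
    return preop, followup, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: per-grade resorption-fraction distributions mirroring the validation
#: cohort's per-grade mean losses (12.3% / 31.5% / 58.3%)
COHORT_FRACTION_PARAMS = {
    1: (0.123, 0.06),
    2: (0.315, 0.09),
    3: (0.583, 0.12),
}
COHORT_N_PER_GRADE = {1: 8, 2: 18, 3: 5}


def cohort_specs(seed: int, n_per_grade: dict | None = None,
                 noise_sigma: float = 20.0) -> list[tuple[int, PhantomSpec]]:
    """Seeded phantom specs stratified like the validation cohort."""
    n_per_grade = n_per_grade or COHORT_N_PER_GRADE
    rng = np.random.default_rng(seed)
    specs = []
    for grade, n in sorted(n_per_grade.items()):
        mu, sd = COHORT_FRACTION_PARAMS[grade]
        for _ in range(n):
            frac = float(np.clip(rng.normal(mu, sd), 0.02, 0.95))
            specs.append((grade, PhantomSpec(
                resorption_fraction=frac,
                resorption_gradient="superficial" if grade >= 2 else "superior",
                interscan_transform=random_interscan_transform(
                    int(rng.integers(0, 2**31 - 1))),
                noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
            )))
    return specs


def generate_cohort(seed: int = 0, n_per_grade: dict | None = None) -> pd.DataFrame:
    """Ground-truth rating table for a stratified phantom cohort.

    Columns: patient_id, zhu_grade (stratum), volume_t0_mm3,
    volume_followup_mm3, resorption_pct, expected_zhu_grade (geometric).
    Volumes are exact voxel-count truths; use the full pipeline for
    measured values.
    """
    rows = []
    for i, (grade, spec) in enumerate(cohort_specs(seed, n_per_grade)):
        _, _, truth = generate_phantom_pair(spec)
        rows.append({
            "patient_id": f"P{i:03d}",
            "zhu_grade": grade,
            "volume_t0_mm3": truth.graft_volume_t0,
            "volume_followup_mm3": truth.graft_volume_followup,
            "resorption_pct": truth.resorption_pct,
            "expected_zhu_grade": truth.expected_zhu_grade,
        })
    return pd.DataFrame(rows)
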