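"""Rigid surface registration of the pre-operative scapula onto follow-up.

The two scapulae genuinely differ: the coracoid has been harvested on the
follow-up side and a graft sits on the anterior glenoid. A *trimmed* ICP
keeps those non-overlapping regions from biasing the fit; the trim
fraction is annealed (20% -> 10% -> outlier-only) because a fixed trim
creates local minima at moderate misalignment. Correspondences are nearest
points on triangles (not nearest vertices); pose updates are Kabsch solves
during a short warm-up, then trust-region-clipped linearized
point-to-plane steps, which do not stall in the tangential sliding modes
of a blade-like bone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._mesh import SurfaceQuery, kabsch, rotation_about_axis, rotation_angle_deg
from .errors import MeshError

log = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """Rotation + translation mapping points between physical frames (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise MeshError("rotation must be orthonormal with det = +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (self.rotation @ points.T).T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    def to_dict(self) -> dict:
        return {"matrix_4x4_row_major": self.as_matrix().tolist()}


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "rms_residual_mm": self.rms_residual,
            "iterations": self.iterations,
            "converged": self.converged,
        }


def apply_transform(mesh: trimesh.Trimesh, transform: RigidTransform) -> trimesh.Trimesh:
    """Rigidly move a mesh; enclosed volume is preserved exactly."""
    out = mesh.copy()
    out.vertices = transform.apply(mesh.vertices)
    return out


def _principal_axes(points: np.ndarray):
    """Centroid, eigenvalues (desc) and sign-disambiguated axes of a cloud.

    Axis signs are chosen so the third central moment of the projections is
    non-negative; near-symmetric axes (|skew| ~ 0) keep an arbitrary but
    deterministic sign.
    """
    c = points.mean(axis=0)
    X = points - c
    cov = X.T @ X / len(X)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    skew = np.zeros(3)
    for i in range(3):
        proj = X @ evecs[:, i]
        skew[i] = np.mean(proj**3)
        if skew[i] < 0:
            evecs[:, i] = -evecs[:, i]
            skew[i] = -skew[i]
    if np.linalg.det(evecs) < 0:
        j = int(np.argmin(np.abs(skew)))
        evecs[:, j] = -evecs[:, j]
    return c, evals, evecs, skew


def initialize_alignment(moving: trimesh.Trimesh, fixed: trimesh.Trimesh,
                         n_score_samples: int = 400) -> RigidTransform:
    """Initial pose from centroids and principal axes.

    Principal-axis pairing leaves a two-fold sign ambiguity per axis
    (four right-handed candidates). Third central moments disambiguate in
    principle, but are unreliable when the shapes genuinely differ, so all
    four candidates are scored by mean nearest-vertex distance on a
    deterministic subsample and the best is returned. Falls back to
    centroid-only alignment (with a warning) when the inertia spectrum is
    degenerate — two nearly equal eigenvalues make axis pairing
    meaningless.
    """
    if len(moving.vertices) == 0 or len(fixed.vertices) == 0:
        raise MeshError("initialize_alignment requires non-empty meshes")
    mv = moving.vertices.view(np.ndarray)
    fv = fixed.vertices.view(np.ndarray)
    cm, evm, Rm, _ = _principal_axes(mv)
    cf, evf, Rf, _ = _principal_axes(fv)
    rel_gap = np.min(np.abs(np.diff(evm))) / max(evm[0], 1e-30)
    if rel_gap < 1e-9:
        warnings.warn("degenerate inertia tensor; centroid-only initialization")
        return RigidTransform(np.eye(3), cf - cm)

    from scipy.spatial import cKDTree

    rng = np.random.default_rng(0)
    sample = mv[rng.choice(len(mv), size=min(n_score_samples, len(mv)), replace=False)]
    tree = cKDTree(fv)
    best = None
    for flips in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = (Rf * np.asarray(flips)) @ Rm.T
        t = cf - R @ cm
        d, _ = tree.query((R @ sample.T).T + t)
        score = float(np.mean(d))
        if best is None or score < best[0]:
            best = (score, RigidTransform(R, t))
    return best[1]


def _point_to_plane_step(moved, targets, normals,
                         max_angle_rad: float = 0.03,
                         max_translation_mm: float = 1.5) -> RigidTransform:
    """One linearized point-to-plane update (small-angle approximation).

    The step is clipped to a trust region: the linearization is only valid
    for small pose increments, and an unclipped solve from a coarse pose
    can overshoot into a different basin.
    """
    centroid = moved.mean(axis=0)
    local = moved - centroid
    b = np.einsum("ij,ij->i", targets - moved, normals)
    A = np.hstack([np.cross(local, normals), normals])
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    omega, t = x[:3], x[3:]
    angle = np.linalg.norm(omega)
    if angle > max_angle_rad:
        t = t * (max_angle_rad / angle)
        omega = omega * (max_angle_rad / angle)
        angle = max_angle_rad
    tn = np.linalg.norm(t)
    if tn > max_translation_mm:
        t = t * (max_translation_mm / tn)
    if angle < 1e-15:
        R = np.eye(3)
    else:
        R = rotation_about_axis(omega / angle, angle)
    # rotation about the correspondence centroid, not the origin
    return RigidTransform(R, t + centroid - R @ centroid)


def icp_register(
    moving: trimesh.Trimesh,
    fixed: trimesh.Trimesh,
    init: RigidTransform | None = None,
    max_iterations: int = 400,
    tolerance: float = 1e-4,
    trim_fraction: float = 0.2,
    sample_points: int = 1500,
    seed: int = 0,
    exclude_moving: np.ndarray | None = None,
    point_to_plane: bool = True,
) -> RegistrationResult:
    """Trimmed point-to-surface ICP mapping `moving` into `fixed`'s frame.

    Parameters
    ----------
    trim_fraction : float
        Fraction of worst correspondences discarded each iteration; 0.2 by
        default because the two bones differ by construction (harvested
        coracoid, added graft).
    exclude_moving : bool array over moving vertices, optional
        Vertices to ignore entirely (e.g. the marked coracoid region).
    seed : int
        Seed for the deterministic vertex subsample.

    Non-convergence returns ``converged=False`` with a warning, never an
    exception.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    init = init or RigidTransform.identity()
    pts = moving.vertices.view(np.ndarray)
    if exclude_moving is not None:
        pts = pts[~np.asarray(exclude_moving, dtype=bool)]
    if len(pts) == 0 or len(fixed.faces) == 0:
        raise MeshError("icp_register requires non-empty meshes")
    rng = np.random.default_rng(seed)
    if len(pts) > sample_points:
        pts = pts[rng.choice(len(pts), size=sample_points, replace=False)]

    query = SurfaceQuery(fixed)
    transform = init
    prev_rms = np.inf
    rms = np.inf
    converged = False
    it = 0
    warmup = 5
    # trimming is annealed: converge under aggressive trimming first, then
    # relax toward outlier-only rejection. A fixed trim fraction creates
    # local minima — at moderate misalignment the high-curvature points
    # that pin down rotation are exactly the worst-distance ones.
    phases = [trim_fraction, trim_fraction / 2.0, 0.0]
    phase = 0
    for it in range(1, max_iterations + 1):
        moved = transform.apply(pts)
        closest, dist, normals = query.closest(moved, return_normals=True)
        if phases[phase] > 0:
            cutoff = max(
                np.quantile(dist, 1.0 - phases[phase]),
                3.0 * np.median(dist),
            )
        elif exclude_moving is not None:
            # the caller vouched that every remaining point has a true
            # counterpart; keep everything in the final phase
            cutoff = np.inf
        else:
            cutoff = 3.0 * max(float(np.median(dist)), 1e-9)
        keep = np.flatnonzero(dist <= cutoff)
        if len(keep) < 3:
            keep = np.argsort(dist)[: max(3, len(dist) // 2)]
        if point_to_plane and it > warmup:
            # linearized point-to-plane step: robust point-to-point warm-up
            # first, then the fast normal-projected solve that does not
            # stall in tangential sliding modes
            delta = _point_to_plane_step(moved[keep], closest[keep], normals[keep])
            new_transform = delta.compose(transform)
        else:
            R, t = kabsch(pts[keep], closest[keep])
            new_transform = RigidTransform(R, t)
        # pose increment = largest point displacement between iterations;
        # with surface noise the rms plateaus while the pose can still be
        # sliding, so rms stagnation alone must not count as convergence
        step = float(np.linalg.norm(new_transform.apply(pts) - moved, axis=1).max())
        transform = new_transform
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        if abs(prev_rms - rms) < tolerance and step < 10 * tolerance:
            if phase < len(phases) - 1:
                phase += 1
                prev_rms = np.inf
                continue
            converged = True
            break
        prev_rms = rms
    if not converged:
        warnings.warn(
            f"ICP did not converge in {max_iterations} iterations (rms {rms:.4g} mm)"
        )
    return RegistrationResult(transform, rms, it, converged)


def rotation_error_deg(estimate: RigidTransform, truth: RigidTransform) -> float:
    return rotation_angle_deg(estimate.rotation @ truth.rotation.T)


def translation_error_mm(estimate: RigidTransform, truth: RigidTransform) -> float:
    return float(np.linalg.norm(estimate.translation - truth.translation))
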