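"""Internal geometry kernel.

Small, dependency-light implementations of the mesh primitives the
morphometry needs: a plane cut that caps both halves with planar lids
(conserving total enclosed volume to floating precision), slice-based
voxelization of a closed surface onto a physical grid, ray-casting point
containment, and KD-tree accelerated point-to-triangle closest-point
queries used by the ICP.

The cap construction exploits two facts: (1) both halves share the exact
same edge-intersection points, and (2) for a *planar* cap the divergence-
theorem volume depends only on the boundary loop, not on how the loop is
triangulated, so a simple fan from the loop centroid is exact even for
non-convex cross sections.
"""

from __future__ import annotations

import numpy as np
import trimesh
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree

from .errors import MeshError, NonWatertightError


# ---------------------------------------------------------------------------
# rigid-motion helpers
# ---------------------------------------------------------------------------

def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, Rodrigues form."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Geodesic angle of a rotation matrix, in degrees."""
    c = (np.trace(rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def kabsch(source: np.ndarray, target: np.ndarray, weights=None):
    """Least-squares rigid transform (R, t) with R @ source + t ~= target."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if weights is None:
        weights = np.ones(len(source))
    w = weights / weights.sum()
    cs = (source * w[:, None]).sum(axis=0)
    ct = (target * w[:, None]).sum(axis=0)
    H = (w[:, None] * (source - cs)).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ct - R @ cs
    return R, t


# ---------------------------------------------------------------------------
# plane cut with planar cap
# ---------------------------------------------------------------------------

def _chain_loops(segments: dict):
    """Chain directed segments {start_key: (end_key, p_start, p_end)} into loops.

    Returns a list of loops, each an (L, 3) array of points (closed
    implicitly; last point connects back to the first).
    """
    loops = []
    remaining = dict(segments)
    while remaining:
        start_key, (end_key, p_start, p_end) = next(iter(remaining.items()))
        del remaining[start_key]
        pts = [p_start, p_end]
        key = end_key
        while key != start_key:
            if key not in remaining:
                # open chain: numerical degeneracy; drop it
                pts = None
                break
            nxt_key, _, p_next = remaining.pop(key)
            pts.append(p_next)
            key = nxt_key
        if pts is not None and len(pts) >= 4:
            loops.append(np.asarray(pts[:-1]))  # last point == first
        elif pts is not None and len(pts) == 3:
            loops.append(np.asarray(pts[:-1]))
    return loops


def plane_cut(mesh: trimesh.Trimesh, point, normal):
    """Cut a watertight mesh by the plane through `point` with unit `normal`.

    Returns ``(below, above)`` trimesh objects, where *below* is the side
    with ``(x - point) . normal < 0``. Both halves are capped with planar
    lids so that ``volume(below) + volume(above) == volume(mesh)`` to
    floating precision. Either half may be empty (0 faces).
    """
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if not mesh.is_watertight:
        raise NonWatertightError(
            "plane_cut requires a watertight mesh",
            boundary_edges=int(len(mesh.edges) - len(mesh.edges_unique) * 2) if len(mesh.edges) else -1,
        )

    V = mesh.vertices.view(np.ndarray)
    F = mesh.faces.view(np.ndarray)
    d = (V - point) @ normal
    scale = max(1.0, float(np.abs(d).max()))
    # nudge on-plane vertices to the positive side for a deterministic split
    d = np.where(np.abs(d) < 1e-12 * scale, 1e-12 * scale, d)
    above_v = d > 0

    n_above = above_v[F].sum(axis=1)
    faces_below = F[n_above == 0]
    faces_above = F[n_above == 3]
    crossing = F[(n_above == 1) | (n_above == 2)]

    if len(crossing) == 0:
        empty = trimesh.Trimesh()
        if len(faces_above) == 0:
            return mesh.copy(), empty
        return empty, mesh.copy()

    new_pts: list[np.ndarray] = []
    edge_point_id: dict[tuple, int] = {}

    def edge_point(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in edge_point_id:
            t = d[i] / (d[i] - d[j])
            new_pts.append(V[i] + t * (V[j] - V[i]))
            edge_point_id[key] = len(V) + len(new_pts) - 1
        return edge_point_id[key], key

    tri_below, tri_above = [], []
    seg_below: dict[tuple, tuple] = {}

    for tri in crossing:
        poly_b, poly_a = [], []
        plane_keys = []
        for k in range(3):
            i, j = tri[k], tri[(k + 1) % 3]
            (poly_b if d[i] < 0 else poly_a).append(i)
            if (d[i] > 0) != (d[j] > 0):
                pid, key = edge_point(i, j)
                poly_b.append(pid)
                poly_a.append(pid)
                plane_keys.append((pid, key))
        for poly, sink in ((poly_b, tri_below), (poly_a, tri_above)):
            if len(poly) == 3:
                sink.append(poly)
            elif len(poly) == 4:
                sink.append([poly[0], poly[1], poly[2]])
                sink.append([poly[0], poly[2], poly[3]])
        # directed boundary segment of the below-side surface: in the below
        # polygon the two plane points appear in winding order
        ids_in_b = [pid for pid in poly_b if pid >= len(V)]
        if len(ids_in_b) == 2:
            keys = {pid: key for pid, key in plane_keys}
            p0, p1 = ids_in_b
            # consecutive order along poly_b winding
            i0, i1 = poly_b.index(p0), poly_b.index(p1)
            if (i0 + 1) % len(poly_b) != i1:
                p0, p1 = p1, p0
            seg_below[keys[p0]] = (keys[p1], p0, p1)

    all_vertices = np.vstack([V] + new_pts) if new_pts else V.copy()

    # cap loops: chain by edge key; store point *ids* to keep both caps
    # geometrically identical
    id_segments = {k: (v[0], v[1], v[2]) for k, v in seg_below.items()}
    loops_ids = []
    remaining = dict(id_segments)
    while remaining:
        start_key, (end_key, p_start, p_end) = next(iter(remaining.items()))
        del remaining[start_key]
        ids = [p_start, p_end]
        key = end_key
        ok = True
        while key != start_key:
            if key not in remaining:
                ok = False
                break
            nxt_key, _, p_next = remaining.pop(key)
            ids.append(p_next)
            key = nxt_key
        if ok and len(ids) >= 4:
            loops_ids.append(ids[:-1])

    cap_below, cap_above = [], []
    centroid_ids = []
    for ids in loops_ids:
        pts = all_vertices[ids]
        centroid = pts.mean(axis=0)
        all_vertices = np.vstack([all_vertices, centroid[None, :]])
        cid = len(all_vertices) - 1
        centroid_ids.append(cid)
        n = len(ids)
        for k in range(n):
            a, b = ids[k], ids[(k + 1) % n]
            # below surface boundary is traversed a->b in its winding; the cap
            # closing the below side must traverse b->a
            cap_below.append([cid, b, a])
            cap_above.append([cid, a, b])

    def build(tris_whole, tris_split, caps):
        faces = [np.asarray(t).reshape(-1, 3) for t in (tris_whole, tris_split, caps) if len(t)]
        if not faces:
            return trimesh.Trimesh()
        faces = np.vstack(faces)
        m = trimesh.Trimesh(vertices=all_vertices, faces=faces, process=False)
        m.remove_unreferenced_vertices()
        m.merge_vertices()
        # drop faces that collapsed to a repeated vertex id; their half-edge
        # pairs cancel, so watertightness is preserved
        f = m.faces
        keep = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
        if not keep.all():
            m.update_faces(keep)
        return m

    below = build(faces_below, tri_below, cap_below)
    above = build(faces_above, tri_above, cap_above)
    return below, above


def plane_section_loops(mesh: trimesh.Trimesh, point, normal):
    """Closed cross-section loops of a mesh with a plane, as (L, 3) arrays."""
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    V = mesh.vertices.view(np.ndarray)
    F = mesh.faces.view(np.ndarray)
    d = (V - point) @ normal
    scale = max(1.0, float(np.abs(d).max()))
    d = np.where(np.abs(d) < 1e-12 * scale, 1e-12 * scale, d)
    mask = ((d[F] > 0).sum(axis=1) % 3) != 0
    segments: dict[tuple, tuple] = {}
    cache: dict[tuple, np.ndarray] = {}

    def epoint(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in cache:
            t = d[i] / (d[i] - d[j])
            cache[key] = V[i] + t * (V[j] - V[i])
        return key, cache[key]

    for tri in F[mask]:
        below_order = []
        for k in range(3):
            i, j = tri[k], tri[(k + 1) % 3]
            if d[i] < 0:
                below_order.append(("v", i))
            if (d[i] > 0) != (d[j] > 0):
                key, p = epoint(i, j)
                below_order.append(("e", key, p))
        epts = [item for item in below_order if item[0] == "e"]
        if len(epts) != 2:
            continue
        i0 = below_order.index(epts[0])
        i1 = below_order.index(epts[1])
        first, second = epts[0], epts[1]
        if (i0 + 1) % len(below_order) != i1:
            first, second = second, first
        segments[first[1]] = (second[1], first[2], second[2])
    return _chain_loops(segments)


# ---------------------------------------------------------------------------
# voxelization / containment
# ---------------------------------------------------------------------------

def voxelize_on_grid(mesh: trimesh.Trimesh, origin, spacing, shape) -> np.ndarray:
    """Rasterize a closed mesh onto an axis-aligned grid of voxel centres.

    `origin` is the physical position of voxel (0,0,0); grid axes are the
    physical axes (identity direction). Returns a boolean (ni, nj, nk)
    array using the even-odd rule per z-slice.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    out = np.zeros(tuple(shape), dtype=bool)
    if len(mesh.faces) == 0:
        return out
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    pts2d = np.column_stack(
        [np.repeat(xs, len(ys)), np.tile(ys, len(xs))]
    )
    zmin, zmax = mesh.bounds[0][2], mesh.bounds[1][2]
    for k in range(shape[2]):
        z = origin[2] + spacing[2] * k
        if z < zmin or z > zmax:
            continue
        loops = plane_section_loops(mesh, [0.0, 0.0, z + 1e-7 * spacing[2]], [0.0, 0.0, 1.0])
        if not loops:
            continue
        inside = np.zeros(len(pts2d), dtype=bool)
        for loop in loops:
            path = MplPath(loop[:, :2])
            lo = loop[:, :2].min(axis=0) - 1e-9
            hi = loop[:, :2].max(axis=0) + 1e-9
            cand = np.flatnonzero(
                (pts2d[:, 0] >= lo[0]) & (pts2d[:, 0] <= hi[0])
                & (pts2d[:, 1] >= lo[1]) & (pts2d[:, 1] <= hi[1])
            )
            if len(cand) == 0:
                continue
            inside[cand] ^= path.contains_points(pts2d[cand])
        out[:, :, k] = inside.reshape(shape[0], shape[1])
    return out


def contains_points(mesh: trimesh.Trimesh, points: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Point-in-mesh test by +z ray-crossing parity (Moller-Trumbore).

    Intended for moderate point counts (screw-surface samples etc.); grids
    should use :func:`voxelize_on_grid`.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(mesh.faces) == 0:
        return np.zeros(len(points), dtype=bool)
    tri = mesh.triangles.view(np.ndarray)  # (T, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    direction = np.array([0.0, 0.0, 1.0])
    h = np.cross(direction, e2)  # (T, 3)
    a = np.einsum("tj,tj->t", e1, h)
    valid_tri = np.abs(a) > 1e-12
    inv_a = np.where(valid_tri, 1.0 / np.where(valid_tri, a, 1.0), 0.0)
    result = np.zeros(len(points), dtype=bool)
    # tiny deterministic jitter to dodge edge/vertex hits
    pts = points + np.array([1.3e-7, 2.7e-7, 0.0])
    for start in range(0, len(pts), chunk):
        p = pts[start : start + chunk]  # (P, 3)
        s = p[:, None, :] - v0[None, :, :]  # (P, T, 3)
        u = np.einsum("ptj,tj->pt", s, h) * inv_a
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("ptj,j->pt", q, direction) * inv_a
        t = np.einsum("ptj,tj->pt", q, e2) * inv_a
        hit = (
            valid_tri[None, :]
            & (u >= 0.0) & (u <= 1.0)
            & (v >= 0.0) & (u + v <= 1.0)
            & (t > 1e-9)
        )
        result[start : start + chunk] = (hit.sum(axis=1) % 2).astype(bool)
    return result


# ---------------------------------------------------------------------------
# closest point on surface
# ---------------------------------------------------------------------------

class SurfaceQuery:
    """KD-tree accelerated nearest point-on-triangle queries."""

    def __init__(self, mesh: trimesh.Trimesh, k: int = 12):
        if len(mesh.faces) == 0:
            raise MeshError("SurfaceQuery requires a mesh with faces")
        self.triangles = mesh.triangles.view(np.ndarray)
        self.centroids = self.triangles.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(k, len(self.centroids))

    def closest(self, points: np.ndarray, return_normals: bool = False):
        """Return (closest_points, distances[, unit normals]) per query point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self.tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        P, K = idx.shape
        cand_tris = self.triangles[idx.ravel()]  # (P*K, 3, 3)
        rep_pts = np.repeat(points, K, axis=0)
        cp = trimesh.triangles.closest_point(cand_tris, rep_pts).reshape(P, K, 3)
        dist = np.linalg.norm(cp - points[:, None, :], axis=2)
        best = np.argmin(dist, axis=1)
        rows = np.arange(P)
        if not return_normals:
            return cp[rows, best], dist[rows, best]
        tri = self.triangles[idx[rows, best]]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1)
        n = n / np.where(norm > 1e-300, norm, 1.0)[:, None]
        return cp[rows, best], dist[rows, best], n


def distance_point_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points (N, 3) to the segment [a, b]."""
    points = np.atleast_2d(points)
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)
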