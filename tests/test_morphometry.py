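"""Virtual osteotomy, volumetry, resorption metrics, placement, grading."""

import numpy as np
import pytest
import trimesh

from graftmorph.errors import NonWatertightError, UndefinedStatisticError
from graftmorph.graft_morphometry import (
    GraftPair,
    OsteotomyPlane,
    ScrewModel,
    ZhuGrade,
    compute_resorption,
    cut_mesh,
    fit_osteotomy_plane,
    fit_screw,
    mesh_volume,
    place_graft,
    regional_resorption,
    zhu_grade,
)
from graftmorph.io_formats import BinaryMask


# -- volumetry ---------------------------------------------------------------

def test_mesh_volume_unit_cube(unit_cube):
    assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)


def test_mesh_volume_icosphere_within_half_percent():
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    analytic = 4.0 / 3.0 * np.pi * 1000.0
    assert abs(mesh_volume(mesh) - analytic) / analytic < 0.005


def test_mesh_volume_translation_invariant(icosphere):
    moved = icosphere.copy()
    moved.apply_translation([123.0, -45.0, 6.0])
    rel = abs(mesh_volume(moved) - mesh_volume(icosphere)) / mesh_volume(icosphere)
    assert rel < 1e-9


def test_mesh_volume_rejects_open_mesh(unit_cube):
    open_box = unit_cube.copy()
    open_box.update_faces(np.arange(len(open_box.faces)) != 0)
    with pytest.raises(NonWatertightError) as exc:
        mesh_volume(open_box)
    assert exc.value.boundary_edges > 0


# -- resorption metrics ------------------------------------------------------

def test_resorption_cohort_totals():
    mm3, pct = compute_resorption(2931.0, 2010.0)
    assert mm3 == pytest.approx(921.0)
    assert pct == pytest.approx(100 * 921 / 2931, abs=1e-9)


def test_resorption_zero_and_ratio_convention():
    assert compute_resorption(100.0, 100.0) == (0.0, 0.0)
    mm3, pct = compute_resorption(2724.0, 2369.0)
    assert mm3 == pytest.approx(355.0)
    assert pct == pytest.approx(13.03, abs=0.005)


def test_resorption_negative_allowed_growth():
    mm3, pct = compute_resorption(1000.0, 1200.0)
    assert mm3 == -200.0 and pct == pytest.approx(-20.0)


def test_resorption_zero_t0_undefined():
    with pytest.raises(UndefinedStatisticError):
        compute_resorption(0.0, 10.0)


# -- osteotomy ---------------------------------------------------------------

def test_cut_unit_cube_midplane(unit_cube):
    plane = OsteotomyPlane([0, 0, 0], [1, 0, 0])
    graft, remainder = cut_mesh(unit_cube, plane)
    assert graft.is_watertight and remainder.is_watertight
    assert mesh_volume(graft) == pytest.approx(0.5, abs=1e-9)
    assert mesh_volume(remainder) == pytest.approx(0.5, abs=1e-9)


def test_cut_plane_outside_returns_empty_graft(unit_cube):
    plane = OsteotomyPlane([5, 0, 0], [1, 0, 0])
    with pytest.warns(UserWarning, match="does not intersect"):
        graft, remainder = cut_mesh(unit_cube, plane)
    assert len(graft.faces) == 0
    assert mesh_volume(remainder) == pytest.approx(1.0)


def test_cut_conservation_random_cases():
    from conftest import random_test_mesh

    rng = np.random.default_rng(12)
    for _ in range(10):
        mesh = random_test_mesh(rng)
        n = rng.normal(size=3)
        p = mesh.centroid + rng.uniform(-0.3, 0.3) * mesh.extents
        graft, rem = cut_mesh(mesh, OsteotomyPlane(p, n))
        total = (mesh_volume(graft) if len(graft.faces) else 0.0) + (
            mesh_volume(rem) if len(rem.faces) else 0.0
        )
        assert abs(total - mesh_volume(mesh)) / mesh_volume(mesh) < 1e-6


def test_cut_phantom_graft_matches_analytic(preop_mesh, phantom_clean):
    spec = phantom_clean[0]
    graft, _ = cut_mesh(preop_mesh, spec.osteotomy_plane)
    analytic = spec.analytic_graft_volume
    assert abs(mesh_volume(graft) - analytic) / analytic < 0.02


def test_plane_fit_from_landmarks():
    rng = np.random.default_rng(3)
    normal = np.array([0.3, -0.5, 0.8])
    normal /= np.linalg.norm(normal)
    basis = np.linalg.svd(normal[None, :])[2][1:]
    pts = np.array([3.0, 1.0, -2.0])[None, :] + rng.normal(size=(8, 2)) @ basis
    plane = fit_osteotomy_plane(pts, orient_toward=np.array([3, 1, -2]) + 5 * normal)
    assert abs(abs(plane.normal @ normal) - 1.0) < 1e-9
    assert plane.normal @ normal > 0
    with pytest.raises(ValueError):
        fit_osteotomy_plane(pts[:2])


# -- screw fitting -----------------------------------------------------------

def make_screw_mask(shaft_r=2.25, head_r=4.0, head_len=3.0, length=28.0, spacing=0.5):
    n = int(length / spacing) + 12
    m = int(2 * head_r / spacing) + 12
    idx = np.indices((n, m, m)).reshape(3, -1).T * spacing
    axis_off = m * spacing / 2
    t = idx[:, 0] - 2.0
    radial = np.linalg.norm(idx[:, 1:] - axis_off, axis=1)
    shaft = (radial <= shaft_r) & (t >= 0) & (t <= length - head_len)
    head = (radial <= head_r) & (t > length - head_len) & (t <= length)
    return BinaryMask((shaft | head).reshape(n, m, m), (spacing,) * 3, (0, 0, 0))


def test_fit_screw_recovers_geometry():
    mask = make_screw_mask()
    screw = fit_screw(mask)
    assert abs(abs(screw.axis[0]) - 1.0) < 0.01
    assert screw.axis[0] > 0  # head at +x end
    assert screw.shaft_radius == pytest.approx(2.25, abs=0.5)
    assert screw.head_radius == pytest.approx(4.0, abs=0.6)
    assert screw.length == pytest.approx(28.0, abs=1.5)
    assert screw.head_length == pytest.approx(3.0, abs=1.5)


def test_screw_model_invariants():
    with pytest.raises(ValueError):
        ScrewModel(axis=[1, 0, 0], tip=[0, 0, 0], length=20.0,
                   shaft_radius=3.0, head_center=[18, 0, 0],
                   head_radius=2.0, head_length=3.0)


# -- Zhu grading -------------------------------------------------------------

def reference_screw():
    return ScrewModel(
        axis=[1.0, 0.0, 0.0], tip=[-10.0, 0.0, 0.0], length=28.0,
        shaft_radius=2.25, head_center=[16.5, 0.0, 0.0],
        head_radius=4.0, head_length=3.0,
    )


def box_graft(x0, x1, half=8.0):
    b = trimesh.creation.box(
        extents=(x1 - x0, 2 * half, 2 * half),
        transform=trimesh.transformations.translation_matrix(
            [(x0 + x1) / 2, 0, 0]),
    )
    return b


def test_grade0_head_buried_in_large_graft():
    graft = box_graft(-8.0, 20.0)  # encloses head entirely
    assert zhu_grade(graft, reference_screw()) == 0


def test_grade1_head_exposed_shaft_covered():
    graft = box_graft(-8.0, 15.0)  # up to the head base, shaft covered
    assert zhu_grade(graft, reference_screw(), shaft_span_mm=22.0) == 1


def test_grade2_shaft_partially_exposed():
    graft = box_graft(-8.0, 6.0)  # half the shaft span exposed
    assert zhu_grade(graft, reference_screw(), shaft_span_mm=22.0) == 2


def test_grade3_empty_or_distant_graft():
    assert zhu_grade(trimesh.Trimesh(), reference_screw()) == 3
    distant = box_graft(-8.0, 15.0)
    distant.apply_translation([0, 50.0, 0])  # > 2 mm from the shaft
    assert zhu_grade(distant, reference_screw()) == 3


def test_overall_grade_is_max_over_screws():
    assert ZhuGrade.from_screws([1, 3]).overall == 3
    assert ZhuGrade.from_screws([0, 0]).overall == 0
    assert ZhuGrade.from_screws([2, 1]).per_screw == (2, 1)


# -- regional mapping --------------------------------------------------------

def test_regional_identical_meshes_zero(icosphere):
    out = regional_resorption(icosphere, icosphere, pitch=1.0)
    assert set(out) == {"superior", "inferior", "medial", "lateral",
                        "superficial", "deep"}
    assert all(v == 0.0 for v in out.values())


def test_regional_empty_followup_100(icosphere):
    out = regional_resorption(icosphere, trimesh.Trimesh(), pitch=1.0)
    assert all(v == 100.0 for v in out.values())


def test_regional_superior_half_removed(icosphere):
    lower, _ = cut_mesh(icosphere, OsteotomyPlane([0, 0, 0], [0, 0, 1]))
    out = regional_resorption(icosphere, lower, pitch=0.5)
    assert out["superior"] > 95.0
    assert out["inferior"] < 5.0
    assert 40.0 < out["medial"] < 60.0


# -- placement ---------------------------------------------------------------

def test_place_graft_identity_when_already_in_place(preop_mesh, phantom_clean):
    spec = phantom_clean[0]
    graft, remainder = cut_mesh(preop_mesh, spec.osteotomy_plane)
    result = place_graft(graft, remainder, graft.copy())
    np.testing.assert_allclose(result.transform.as_matrix(), np.eye(4), atol=1e-6)
    assert result.rms_residual < 0.05


def test_place_graft_recovers_known_pose(preop_mesh, phantom_clean):
    from graftmorph._mesh import rotation_about_axis
    from graftmorph.registration import RigidTransform, apply_transform

    spec = phantom_clean[0]
    graft, remainder = cut_mesh(preop_mesh, spec.osteotomy_plane)
    pose = RigidTransform(
        rotation_about_axis([0.1, 0.9, -0.3], np.radians(40.0)), [15.0, -8.0, 4.0]
    )
    reference = apply_transform(graft, pose)
    result = place_graft(graft, remainder, reference,
                         superior_axis=pose.rotation @ spec.osteotomy_plane.normal * -1)
    d = np.linalg.norm(result.graft.vertices - reference.vertices, axis=1)
    assert np.sqrt(np.mean(d**2)) < 0.5


def test_graft_pair_metrics(icosphere, unit_cube):
    pair = GraftPair.from_meshes(icosphere, unit_cube)
    assert pair.volume_t0 == pytest.approx(mesh_volume(icosphere))
    assert pair.resorption_mm3 == pytest.approx(pair.volume_t0 - 1.0)
    assert pair.resorption_pct == pytest.approx(
        100 * pair.resorption_mm3 / pair.volume_t0)
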