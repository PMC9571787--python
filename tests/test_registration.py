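"""Rigid transform algebra, initialization and trimmed-ICP recovery."""

import numpy as np
import pytest
import trimesh

from graftmorph._mesh import rotation_about_axis
from graftmorph.graft_morphometry import cut_mesh
from graftmorph.registration import (
    RigidTransform,
    apply_transform,
    icp_register,
    initialize_alignment,
    rotation_error_deg,
    translation_error_mm,
)


def random_rigid(rng, max_deg=30.0, max_mm=20.0):
    R = rotation_about_axis(rng.normal(size=3), np.radians(rng.uniform(1, max_deg)))
    return RigidTransform(R, rng.uniform(-max_mm, max_mm, size=3))


def test_rigid_transform_algebra():
    rng = np.random.default_rng(0)
    T = random_rigid(rng)
    pts = rng.normal(size=(50, 3)) * 20
    np.testing.assert_allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-9)
    comp = T.compose(T.inverse())
    np.testing.assert_allclose(comp.as_matrix(), np.eye(4), atol=1e-9)
    back = RigidTransform.from_matrix(T.as_matrix())
    np.testing.assert_allclose(back.rotation, T.rotation)


def test_reflection_rejected():
    from graftmorph.errors import MeshError

    with pytest.raises(MeshError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


def test_apply_transform_preserves_volume(icosphere):
    rng = np.random.default_rng(1)
    T = random_rigid(rng)
    moved = apply_transform(icosphere, T)
    assert abs(moved.volume - icosphere.volume) / icosphere.volume < 1e-9


def test_initialize_identity_for_self(preop_mesh):
    T = initialize_alignment(preop_mesh, preop_mesh)
    np.testing.assert_allclose(T.as_matrix(), np.eye(4), atol=1e-9)


def test_initialize_recovers_pure_translation(preop_mesh):
    t = np.array([10.0, -5.0, 3.0])
    moved = apply_transform(preop_mesh, RigidTransform(np.eye(3), t))
    T = initialize_alignment(preop_mesh, moved)
    assert np.linalg.norm(T.translation - t) < 1e-6
    np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)


def test_initialize_within_10deg_of_truth(preop_mesh):
    truth = RigidTransform(
        rotation_about_axis([0.3, -0.8, 0.5], np.radians(25.0)), [5.0, -3.0, 8.0]
    )
    moved = apply_transform(preop_mesh, truth)
    T = initialize_alignment(preop_mesh, moved)
    assert rotation_error_deg(T, truth) < 10.0


def test_initialize_degenerate_falls_back_to_centroid(icosphere):
    with pytest.warns(UserWarning, match="degenerate"):
        T = initialize_alignment(icosphere, icosphere)
    np.testing.assert_allclose(T.rotation, np.eye(3))


def test_icp_identity_on_identical_meshes(preop_mesh):
    res = icp_register(preop_mesh, preop_mesh, seed=0)
    assert res.converged
    assert res.rms_residual < 1e-6
    np.testing.assert_allclose(res.transform.as_matrix(), np.eye(4), atol=1e-9)


def test_icp_recovers_known_transform(preop_mesh):
    truth = RigidTransform(
        rotation_about_axis([0.2, 0.5, -0.8], np.radians(15.0)), [5.0, 4.0, -4.0]
    )
    fixed = apply_transform(preop_mesh, truth)
    init = initialize_alignment(preop_mesh, fixed)
    res = icp_register(preop_mesh, fixed, init, seed=0)
    assert rotation_error_deg(res.transform, truth) < 0.5
    assert translation_error_mm(res.transform, truth) < 0.2


def test_icp_partial_overlap_with_noise(preop_mesh, phantom_clean):
    """Follow-up missing its coracoid (harvested) plus vertex noise."""
    spec = phantom_clean[0]
    _, remainder = cut_mesh(preop_mesh, spec.osteotomy_plane)
    rng = np.random.default_rng(4)
    truth = random_rigid(rng)
    fixed = apply_transform(remainder, truth)
    fixed.vertices += rng.normal(0, 0.3, size=fixed.vertices.shape)
    init = initialize_alignment(preop_mesh, fixed)
    # the caller marks the harvested coracoid region and excludes it
    exclude = spec.osteotomy_plane.signed_distance(preop_mesh.vertices) < 3.0
    res = icp_register(preop_mesh, fixed, init, seed=0, exclude_moving=exclude)
    assert rotation_error_deg(res.transform, truth) < 2.0


def test_icp_rigid_motion_equivariance(preop_mesh):
    """Registering (T o moving) onto fixed returns result o T^-1."""
    rng = np.random.default_rng(7)
    truth = random_rigid(rng, max_deg=20, max_mm=10)
    fixed = apply_transform(preop_mesh, truth)
    base = icp_register(preop_mesh, fixed,
                        initialize_alignment(preop_mesh, fixed), seed=0)
    T = random_rigid(rng, max_deg=15, max_mm=10)
    pre_moved = apply_transform(preop_mesh, T)
    res = icp_register(pre_moved, fixed,
                       initialize_alignment(pre_moved, fixed), seed=0)
    expected = base.transform.compose(T.inverse())
    assert rotation_error_deg(res.transform, expected) < 0.5
    assert np.linalg.norm(res.transform.translation - expected.translation) < 0.5


def test_icp_nonconvergence_warns_not_raises(preop_mesh):
    truth = RigidTransform(rotation_about_axis([1, 0, 0], 0.3), [4.0, 0, 0])
    fixed = apply_transform(preop_mesh, truth)
    with pytest.warns(UserWarning, match="did not converge"):
        res = icp_register(preop_mesh, fixed, max_iterations=2, seed=0)
    assert not res.converged
    assert res.iterations == 2
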