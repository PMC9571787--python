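"""Thresholding, component handling and surface extraction."""

import numpy as np
import pytest

from graftmorph.errors import EmptySegmentationError
from graftmorph.io_formats import BinaryMask, CTVolume
from graftmorph.segmentation import (
    SegmentationParams,
    extract_surface,
    metal_components,
    segment_bone,
    segment_metal,
)


def digital_sphere(radius_mm, spacing=0.75, hu=700.0, background=0.0):
    n = int(2 * radius_mm / spacing) + 9
    idx = np.indices((n, n, n)).reshape(3, -1).T
    centre = (n - 1) / 2 * spacing
    inside = np.linalg.norm(idx * spacing - centre, axis=1) <= radius_mm
    data = np.full(n**3, background, np.float32)
    data[inside] = hu
    return CTVolume(data.reshape(n, n, n), (spacing,) * 3, (0, 0, 0)), int(inside.sum())


def test_bone_mask_volume_matches_analytic_sphere():
    vol, _ = digital_sphere(10.0)
    mask = segment_bone(vol, SegmentationParams(bone_threshold=226))
    analytic = 4.0 / 3.0 * np.pi * 10.0**3
    assert abs(mask.volume_mm3() - analytic) / analytic < 0.03


def test_all_zero_volume_raises_empty_segmentation():
    vol = CTVolume(np.zeros((20, 20, 20), np.float32), (0.75,) * 3, (0, 0, 0))
    with pytest.raises(EmptySegmentationError):
        segment_bone(vol)


def test_bone_and_metal_masks_disjoint_and_screws_excluded(phantom_030):
    _, _, fu, _ = phantom_030
    bone = segment_bone(fu)
    metal = segment_metal(fu)
    assert not (bone.data & metal.data).any()
    assert metal.data.any()


def test_metal_components_two_cylinders_within_5pct():
    spacing = 0.5
    n = 60
    idx = np.indices((n, n, n)).reshape(3, -1).T * spacing
    data = np.zeros(n**3, np.float32)
    r, h = 2.3, 20.0
    # axis off the voxel lattice: boundary voxel centres exactly on the
    # cylinder surface would bias the digitized volume
    for cy in (8.13, 22.21):
        axis_pt = np.array([5.17, cy, 15.23])
        t = idx[:, 0] - axis_pt[0]
        radial = np.linalg.norm(idx[:, 1:] - axis_pt[1:], axis=1)
        data[(radial <= r) & (t >= 0) & (t <= h)] = 3000.0
    vol = CTVolume(data.reshape(n, n, n), (spacing,) * 3, (0, 0, 0))
    metal = segment_metal(vol)
    comps = metal_components(metal)
    assert len(comps) == 2
    analytic = np.pi * r**2 * h
    for c in comps:
        assert abs(c.volume_mm3() - analytic) / analytic < 0.05


def test_preop_scan_without_screws_warns_empty():
    vol, _ = digital_sphere(8.0, hu=700.0)
    with pytest.warns(UserWarning, match="no metal"):
        metal = segment_metal(vol)
    assert not metal.data.any()


def test_segmentation_is_deterministic(phantom_030):
    _, _, fu, _ = phantom_030
    a = segment_bone(fu)
    b = segment_bone(fu)
    assert np.array_equal(a.data, b.data)


def test_extract_surface_cube_volume():
    mask_data = np.zeros((16, 16, 16), bool)
    mask_data[3:13, 3:13, 3:13] = True  # 10x10x10 voxels at 1 mm
    mask = BinaryMask(mask_data, (1.0, 1.0, 1.0), (0, 0, 0))
    mesh = extract_surface(mask)
    assert mesh.is_watertight
    assert abs(mesh.volume - 1000.0) / 1000.0 < 0.05


@pytest.mark.parametrize("radius", [5.0, 10.0, 20.0])
def test_extract_surface_sphere_volume_within_3pct(radius):
    vol, nvox = digital_sphere(radius)
    mask = segment_bone(vol)
    mesh = extract_surface(mask)
    voxel_volume = nvox * 0.75**3
    assert abs(mesh.volume - voxel_volume) / voxel_volume < 0.03


def test_mesh_volume_error_decreases_with_radius():
    errs = []
    for radius in (5.0, 10.0, 20.0):
        vol, nvox = digital_sphere(radius)
        mesh = extract_surface(segment_bone(vol))
        voxel_volume = nvox * 0.75**3
        errs.append(abs(mesh.volume - voxel_volume) / voxel_volume)
    assert errs[0] > errs[2]


def test_single_voxel_mask_yields_closed_positive_mesh():
    data = np.zeros((5, 5, 5), bool)
    data[2, 2, 2] = True
    mesh = extract_surface(BinaryMask(data, (1.0,) * 3, (0, 0, 0)))
    assert mesh.is_watertight
    assert mesh.volume > 0


def test_params_validation():
    with pytest.raises(ValueError):
        SegmentationParams(bone_threshold=300, metal_threshold=200)
    with pytest.raises(ValueError):
        SegmentationParams(min_component_voxels=0)
    with pytest.raises(ValueError):
        SegmentationParams(marching_level=1.5)
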