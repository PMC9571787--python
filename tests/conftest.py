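"""Shared fixtures: phantoms and pipeline runs are expensive, so they are
session-scoped and generated once."""

import warnings

import numpy as np
import pytest
import trimesh

from graftmorph.phantom import (
    GLENOID_LANDMARK,
    PhantomSpec,
    generate_phantom_pair,
    random_interscan_transform,
)
from graftmorph.pipeline import PipelineConfig, run_pipeline


def pipeline_config_for(truth, seed=1, **overrides):
    cfg = PipelineConfig(
        osteotomy_plane=truth.osteotomy_plane,
        coracoid_tip_landmark=truth.coracoid_tip_preop.tolist(),
        glenoid_landmark_preop=GLENOID_LANDMARK.tolist(),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def phantom_030():
    """One moved, noisy phantom pair with 30% superior-weighted resorption."""
    spec = PhantomSpec(
        resorption_fraction=0.3,
        seed=7,
        interscan_transform=random_interscan_transform(3),
    )
    return (spec,) + generate_phantom_pair(spec)


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free, unmoved phantom (zero resorption) for geometry oracles."""
    spec = PhantomSpec(resorption_fraction=0.0, seed=0, noise_sigma=0.0)
    return (spec,) + generate_phantom_pair(spec)


@pytest.fixture(scope="session")
def preop_mesh(phantom_clean):
    from graftmorph.segmentation import SegmentationParams, extract_surface, segment_bone

    _, pre, _, _ = phantom_clean
    params = SegmentationParams()
    return extract_surface(segment_bone(pre, params), params, provenance="pre-op")


@pytest.fixture(scope="session")
def pipeline_report_030(phantom_030):
    spec, pre, fu, truth = phantom_030
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_pipeline(pipeline_config_for(truth), preop=pre, followup=fu)
    return truth, report


@pytest.fixture
def icosphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)


@pytest.fixture
def unit_cube():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


def random_test_mesh(rng):
    """A random watertight solid (sphere, box or capsule), randomly posed."""
    kind = rng.integers(0, 3)
    if kind == 0:
        m = trimesh.creation.icosphere(subdivisions=2, radius=rng.uniform(5, 15))
    elif kind == 1:
        m = trimesh.creation.box(extents=rng.uniform(5, 25, size=3))
    else:
        m = trimesh.creation.capsule(
            radius=rng.uniform(3, 8), height=rng.uniform(5, 20), count=(12, 12)
        )
    from graftmorph._mesh import rotation_about_axis

    R = rotation_about_axis(rng.normal(size=3), rng.uniform(0, np.pi))
    m.vertices = (R @ m.vertices.T).T + rng.uniform(-10, 10, size=3)
    return m
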