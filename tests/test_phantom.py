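"""Phantom generator: determinism, bookkeeping exactness, monotonicity."""

import numpy as np
import pytest

from graftmorph.errors import ConfigError
from graftmorph.phantom import (
    PhantomSpec,
    cohort_specs,
    generate_cohort,
    generate_phantom_pair,
    random_interscan_transform,
)


def test_same_seed_bit_identical():
    a = generate_phantom_pair(PhantomSpec(resorption_fraction=0.25, seed=5))
    b = generate_phantom_pair(PhantomSpec(resorption_fraction=0.25, seed=5))
    assert np.array_equal(a[0].data, b[0].data)
    assert np.array_equal(a[1].data, b[1].data)
    assert a[2].graft_volume_followup == b[2].graft_volume_followup


def test_zero_resorption_truth_volumes_equal(phantom_clean):
    _, _, _, truth = phantom_clean
    assert truth.graft_volume_followup == truth.graft_volume_t0
    assert truth.resorption_pct == 0.0


def test_truth_volume_near_analytic(phantom_clean):
    spec, _, _, truth = phantom_clean
    rel = abs(truth.graft_volume_t0 - spec.analytic_graft_volume)
    assert rel / spec.analytic_graft_volume < 0.03


def test_erosion_strictly_monotone_in_fraction():
    volumes = []
    for f in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6):
        spec = PhantomSpec(resorption_fraction=f, seed=9, noise_sigma=0.0)
        _, _, truth = generate_phantom_pair(spec)
        volumes.append(truth.graft_volume_followup)
        assert truth.resorption_pct == pytest.approx(100 * f, abs=1.0)
    assert all(a > b for a, b in zip(volumes, volumes[1:]))


def test_superior_gradient_concentrates_superiorly():
    spec = PhantomSpec(resorption_fraction=0.3, resorption_gradient="superior",
                       seed=2, noise_sigma=0.0)
    _, _, truth = generate_phantom_pair(spec)
    r = truth.regional_resorbed_pct
    assert r["superior"] > r["inferior"] + 20.0
    assert r["inferior"] < 20.0


def test_noise_does_not_change_truth():
    base = generate_phantom_pair(PhantomSpec(resorption_fraction=0.4, seed=3,
                                             noise_sigma=0.0))[2]
    noisy = generate_phantom_pair(PhantomSpec(resorption_fraction=0.4, seed=3,
                                              noise_sigma=40.0))[2]
    assert base.graft_volume_followup == noisy.graft_volume_followup
    assert base.graft_volume_t0 == noisy.graft_volume_t0


def test_interscan_transform_preserves_truth_volumes():
    still = generate_phantom_pair(PhantomSpec(resorption_fraction=0.3, seed=4))[2]
    moved = generate_phantom_pair(PhantomSpec(
        resorption_fraction=0.3, seed=4,
        interscan_transform=random_interscan_transform(8)))[2]
    rel = abs(moved.graft_volume_t0 - still.graft_volume_t0) / still.graft_volume_t0
    assert rel < 0.02  # only voxelization differs between the two grids


def test_spec_validation():
    with pytest.raises(ConfigError):
        PhantomSpec(resorption_fraction=1.4)
    with pytest.raises(ConfigError):
        PhantomSpec(noise_sigma=-1)
    with pytest.raises(ConfigError):
        PhantomSpec(resorption_gradient="sideways")
    with pytest.raises(ConfigError):
        PhantomSpec(osteotomy_offset=25.0)


def test_cohort_specs_deterministic_and_stratified():
    a = cohort_specs(seed=1)
    b = cohort_specs(seed=1)
    assert len(a) == 31
    assert [g for g, _ in a].count(2) == 18
    for (ga, sa), (gb, sb) in zip(a, b):
        assert ga == gb and sa.resorption_fraction == sb.resorption_fraction


def test_cohort_truth_table_orders_strata():
    df = generate_cohort(seed=1, n_per_grade={1: 3, 2: 3, 3: 3})
    means = df.groupby("zhu_grade")["resorption_pct"].mean()
    assert means[1] < means[2] < means[3]
    df2 = generate_cohort(seed=1, n_per_grade={1: 3, 2: 3, 3: 3})
    assert df.equals(df2)
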