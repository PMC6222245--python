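"""Shared fixtures: synthetic cohorts, tiny atlas volumes, helpers."""

from __future__ import annotations

import numpy as np
import pytest

from seegplan import (
    AffineTransform,
    AVERAGE,
    CohortSpec,
    LabelVolume,
    Point3,
    Trajectory,
    build_model_bundle,
    generate_atlas,
    generate_cohort,
)


def make_trajectory(entry, target, plan_id="p1", electrode_id="e1", space=AVERAGE):
    return Trajectory(
        plan_id=plan_id,
        electrode_id=electrode_id,
        entry=Point3(*entry),
        target=Point3(*target),
        space=space,
    )


def two_slab_volume(nxyz=(20, 20, 20), voxel=1.0, label_a=5, label_b=6):
    """Label A where z > 0, label B where z <= 0; world origin at grid centre."""
    nx, ny, nz = nxyz
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = [-nx * voxel / 2 + voxel / 2,
                  -ny * voxel / 2 + voxel / 2,
                  -nz * voxel / 2 + voxel / 2]
    zs = aff[2, 3] + voxel * np.arange(nz)
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    labels[:, :, zs > 0] = label_a
    labels[:, :, zs <= 0] = label_b
    return LabelVolume(
        labels=labels,
        vox2world=AffineTransform(aff),
        label_table={label_a: "slab_a", label_b: "slab_b"},
    )


def random_invertible_affine(rng, trans=20.0):
    """Random affine with a well-conditioned linear part."""
    while True:
        linear = rng.normal(size=(3, 3))
        if abs(np.linalg.det(linear)) > 0.1:
            break
    m = np.eye(4)
    m[:3, :3] = linear
    m[:3, 3] = rng.uniform(-trans, trans, size=3)
    return AffineTransform(m)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=7)


@pytest.fixture(scope="session")
def default_atlas(default_spec):
    return generate_atlas(default_spec)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def trained_bundle(default_spec, default_atlas, default_cohort):
    """Model bundle mined from the default noisy cohort (no strategies yet)."""
    volume, cfg = default_atlas
    plans, affines, _ = default_cohort
    return build_model_bundle(plans, affines, volume, cfg, seed=default_spec.seed)
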