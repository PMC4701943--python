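import numpy as np
import pytest

from spinekit import (
    FeatureTable,
    SpineRecord,
    make_cylinder_mesh,
    make_mushroom_spine_mesh,
    make_thin_spine_mesh,
)


@pytest.fixture(scope="session")
def cylinder_fixture():
    """Straight capped cylinder, d=1 µm, L=2 µm."""
    return make_cylinder_mesh(1.0, 2.0, n_seg=64)


@pytest.fixture(scope="session")
def mushroom_fixture():
    """Mushroom spine: head 0.8/0.8 µm on a 0.3/1.5 µm neck."""
    return make_mushroom_spine_mesh(0.8, 0.8, 0.3, 1.5, n_seg=64)


@pytest.fixture(scope="session")
def thin_fixture():
    """Long thin protrusion with a sub-threshold 0.3 µm tip."""
    return make_thin_spine_mesh(0.3, 0.3, 0.12, 2.0, n_seg=64)


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-10, 10, size=3)
    return R, t


def small_table(values_by_feature, regions=None):
    """Build a FeatureTable from {feature: [v0, v1, ...]}; None = missing."""
    n = len(next(iter(values_by_feature.values())))
    regions = regions or ["unknown"] * n
    records = []
    for i in range(n):
        feats = {
            k: vals[i]
            for k, vals in values_by_feature.items()
            if vals[i] is not None
        }
        records.append(SpineRecord(f"s{i}", (0.0, 0.0, 0.0), regions[i], feats))
    return FeatureTable(records, list(values_by_feature))
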