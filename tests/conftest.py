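import numpy as np
import pandas as pd
import pytest

from majorload import LoadDataset, Units


def make_dataset(vectors, activity="act", units=Units.BW_PERCENT):
    """Dataset from an (n, 3) array, one activity, sample_index = row."""
    vectors = np.asarray(vectors, dtype=float)
    frame = pd.DataFrame({
        "activity": activity,
        "sample_index": np.arange(len(vectors)),
        "fx": vectors[:, 0], "fy": vectors[:, 1], "fz": vectors[:, 2]})
    return LoadDataset(frame, units)


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix (QR with det fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def three_cluster_dataset():
    """Three tight clusters, pairwise > 2*theta + 2*jitter apart for
    theta=10, jitter=4: the minimal 10-degree cover is exactly 3."""
    from majorload import generate_separated_clusters

    dataset, k = generate_separated_clusters(
        k=3, half_apex_deg=10.0, min_separation_deg=45.0, jitter_deg=4.0,
        seed=7, n_per_cluster=4)
    assert k == 3
    return dataset
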