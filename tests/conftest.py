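import numpy as np
import pytest

from elevatormd import ElevatorParams, make_elevator_trajectory
from elevatormd import landscape as L


def small_params(**kw):
    """A fast, small elevator configuration for unit tests."""
    defaults = dict(
        footprint_radius_cs=10.0,
        footprint_radius_es=12.0,
        box=(64.5, 64.5, 90.0),
        n_waters=60,
        n_frames=20,
        seed=42,
    )
    defaults.update(kw)
    return ElevatorParams(**defaults)


@pytest.fixture(scope="session")
def elevator500():
    """The 500-frame two-state trajectory (dz=1.5 A, rot=7 deg, balanced
    state sampling) used by the end-to-end recovery tests."""
    seq = np.array((["CS"] * 50 + ["ES"] * 50) * 5)
    return make_elevator_trajectory(ElevatorParams(state_sequence=seq, seed=7))


@pytest.fixture(scope="session")
def landscape500(elevator500):
    """PCA model and DBSCAN labels of the 500-frame trajectory (chain A)."""
    tr = elevator500
    residues = L.select_feature_residues()
    features = L.build_distance_features(tr.frames, tr.system, "A", residues)
    model = L.fit_pca(features)
    labels = L.cluster_landscape(model.projections)
    return features, model, labels


@pytest.fixture(scope="session")
def small_elevator():
    seq = np.array((["CS"] * 10 + ["ES"] * 10) * 2)
    return make_elevator_trajectory(small_params(state_sequence=seq))
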