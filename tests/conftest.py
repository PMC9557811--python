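import numpy as np
import pandas as pd
import pytest

from morphopipe import LandmarkDataset, SimulationSpec, gpa, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated raw dataset (balanced 2x2x2 design, p=16)."""
    design = {
        (hab, site, sex): 6
        for hab, site, sex in [
            ("fresh", "A", "F"), ("fresh", "A", "M"),
            ("fresh", "B", "F"), ("fresh", "B", "M"),
            ("marine", "C", "F"), ("marine", "C", "M"),
            ("marine", "D", "F"), ("marine", "D", "M"),
        ]
    }
    spec = SimulationSpec(p=16, design=design, seed=7)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_aligned(small_sim):
    ds, _ = small_sim
    return gpa(ds)


@pytest.fixture()
def tiny_dataset():
    """Hand-written 2-specimen, 4-landmark dataset."""
    coords = np.array(
        [
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            [[0.1, 0.0, 0.0], [1.1, 0.2, 0.0], [0.0, 0.9, 0.1], [0.0, 0.0, 1.2]],
        ]
    )
    return LandmarkDataset(["s1", "s2"], coords)


@pytest.fixture()
def factor_frame():
    return pd.DataFrame(
        {
            "sex": ["F", "M", "F", "M"],
            "habitat": ["fresh", "fresh", "marine", "marine"],
            "site": ["A", "A", "B", "B"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="specimen_id"),
    )


def random_similarity(rng):
    """Random proper rotation, translation and positive scale."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, -1] = -Q[:, -1]
    scale = float(np.exp(rng.uniform(-1, 1)))
    trans = rng.uniform(-10, 10, size=3)
    return Q, scale, trans
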