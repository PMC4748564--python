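import numpy as np
import pytest

from potencyscreen import (
    FingerprintMatrix,
    LabeledDataset,
    SimConfig,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20160209)


@pytest.fixture
def tiny_dataset():
    """4 molecules × 3 bits; bit b0 equals the label, b1 noisy, b2 constant."""
    mat = FingerprintMatrix(
        ["m1", "m2", "m3", "m4"],
        ["b0", "b1", "b2"],
        np.array([[1, 1, 0], [1, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=np.uint8),
    )
    return LabeledDataset(mat, ["active", "active", "inactive", "inactive"])


@pytest.fixture
def planted_dataset():
    """Balanced 200-molecule set whose first bit is present in exactly 90/100
    actives and 10/100 inactives (constructed, not sampled)."""
    n = 100
    col = np.concatenate([np.ones(90), np.zeros(10), np.ones(10), np.zeros(90)])
    noise = np.random.default_rng(7).integers(0, 2, size=(2 * n, 4))
    values = np.column_stack([col, noise]).astype(np.uint8)
    mat = FingerprintMatrix(
        [f"m{i}" for i in range(2 * n)],
        ["planted", "n1", "n2", "n3", "n4"],
        values,
    )
    return LabeledDataset(mat, ["active"] * n + ["inactive"] * n)


@pytest.fixture(scope="session")
def sim_dataset():
    """Moderate synthetic benchmark shared by slower integration tests."""
    cfg = SimConfig(
        n_active=200, n_inactive=200, n_fingerprints=40, n_informative=6,
        seed=42,
    )
    ds, truth = generate_dataset(cfg)
    return ds, truth
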