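import numpy as np
import pytest

from cgrf import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 timepoints with distinct, non-constant rows."""
    return ExpressionMatrix(
        ("g1", "g2", "g3"),
        np.array([0.0, 1.0, 2.0, 4.0]),
        np.array(
            [
                [0.1, 0.9, 1.7, 3.3],
                [2.0, 1.0, 0.5, 0.25],
                [-1.0, 1.0, -1.0, 1.0],
            ]
        ),
    )


def make_blobs(archetypes: np.ndarray, n_per: int, noise_sd: float, seed: int):
    """Genes scattered around archetype rows; returns (matrix, labels)."""
    rng = np.random.default_rng(seed)
    K, T = archetypes.shape
    labels = np.repeat(np.arange(K), n_per)
    values = archetypes[labels] + rng.normal(0.0, noise_sd, size=(K * n_per, T))
    X = ExpressionMatrix(
        tuple(f"g{i}" for i in range(K * n_per)), np.arange(T, dtype=float), values
    )
    return X, labels
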