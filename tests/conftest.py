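import numpy as np
import pytest

from dnamech import GroundTruthSpec, build_ground_truth, sample_trajectory


def random_spd(size: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """Random well-conditioned symmetric positive-definite matrix."""
    A = rng.standard_normal((size, size))
    return scale * (A @ A.T + size * np.eye(size))


@pytest.fixture(scope="session")
def small_truth():
    """Ground-truth non-local model for a 3-bp duplex (N = 30 coordinates)."""
    return build_ground_truth(GroundTruthSpec("GAT"))


@pytest.fixture(scope="session")
def small_trajectory(small_truth):
    return sample_trajectory(small_truth, 5000, seed=42)
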