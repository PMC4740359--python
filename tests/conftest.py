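import numpy as np
import pytest

from provzone.io import MarkerMatrix
from provzone.simulate import FIXTURE_CONFIGS, simulate_dataset


@pytest.fixture
def toy_matrix() -> MarkerMatrix:
    """4 individuals, 2 populations, 3 loci; hand-checkable."""
    bands = np.array(
        [
            [1, 0, 1],
            [0, 0, 1],
            [1, 1, 0],
            [0, 1, 0],
        ],
        dtype=np.int8,
    )
    return MarkerMatrix(["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"], ["L1", "L2", "L3"], bands)


def _dataset(name: str):
    return simulate_dataset(FIXTURE_CONFIGS[name])


@pytest.fixture(scope="session")
def null_dataset():
    """No drift, no selection: all populations share allele frequencies."""
    return _dataset("null")


@pytest.fixture(scope="session")
def ibd_dataset():
    """Strong isolation by distance, no selection."""
    return _dataset("strong_ibd")


@pytest.fixture(scope="session")
def selected_dataset():
    """Isolation by distance plus 5 climate-coupled loci out of 50."""
    return _dataset("selected_loci")


def random_marker_matrix(rng: np.random.Generator, n_pops=3, n_per=4, n_loci=6) -> MarkerMatrix:
    """Random valid marker matrix for property tests."""
    bands = (rng.random((n_pops * n_per, n_loci)) < rng.uniform(0.2, 0.8, n_loci)).astype(np.int8)
    pops = [f"P{k}" for k in range(n_pops) for _ in range(n_per)]
    ids = [f"i{j}" for j in range(n_pops * n_per)]
    return MarkerMatrix(ids, pops, [f"L{j}" for j in range(n_loci)], bands)
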