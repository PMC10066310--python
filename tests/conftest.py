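import math

import numpy as np
import pytest

from divprof import (
    MockSpec,
    ParameterGrid,
    Repertoire,
    make_sequence_repertoire,
)


@pytest.fixture(scope="session")
def grid() -> ParameterGrid:
    """The default published (q, lambda) grid."""
    return ParameterGrid()


@pytest.fixture(scope="session")
def small_grid() -> ParameterGrid:
    """A reduced grid that still contains every sentinel and feature lambda."""
    return ParameterGrid(
        q_values=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, math.inf),
        lambda_values=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0, 16.0, math.inf),
    )


@pytest.fixture
def three_clone_freqs() -> np.ndarray:
    return np.array([0.5, 0.25, 0.25])


@pytest.fixture(scope="session")
def sequence_repertoire() -> Repertoire:
    """A 50-ish clone motif-expanded repertoire shared by oracle tests."""
    spec = MockSpec(S=50, size_law=("dirichlet", 1.0), n_motifs=3,
                    mutations_per_step=2, seed=11)
    return make_sequence_repertoire(spec, sample_id="shared50")


def random_frequencies(rng: np.random.Generator, S: int) -> np.ndarray:
    p = rng.dirichlet(np.full(S, 0.8))
    p = np.maximum(p, 1e-12)
    return p / p.sum()
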