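import numpy as np
import pytest

from occnet import PresenceAbsenceMatrix, bulk_like, generate, particle_like


@pytest.fixture
def tiny_matrix() -> PresenceAbsenceMatrix:
    values = np.array(
        [
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [1, 1, 1, 1],
            [0, 0, 0, 1],
        ]
    )
    return PresenceAbsenceMatrix(values, ["A", "B", "C", "D"], ["s1", "s2", "s3", "s4"])


@pytest.fixture(scope="session")
def bulk_community():
    return generate(bulk_like(seed=1))


@pytest.fixture(scope="session")
def bulk_community_clean():
    return generate(bulk_like(seed=1, noise_rate=0.0))


@pytest.fixture(scope="session")
def particle_community():
    return generate(particle_like(seed=1))


def random_matrix(rng: np.random.Generator, n_frag: int, n_samp: int, p: float = 0.4):
    values = (rng.random((n_frag, n_samp)) < p).astype(int)
    return PresenceAbsenceMatrix(
        values,
        [f"F{i}" for i in range(n_frag)],
        [f"s{j}" for j in range(n_samp)],
    )
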