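import numpy as np
import pytest

from annealdca import Alphabet, PottsEnergy, ScreeningDataset, SequenceRound


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def abc3():
    """Three-state test alphabet (A, C, D)."""
    return Alphabet.generic(3)


def make_random_energy(rng, L, q, pairwise=False, scale=0.5):
    h = rng.normal(0.0, scale, size=(L, q))
    if not pairwise:
        return PottsEnergy(h)
    J = np.zeros((L, L, q, q))
    for i in range(L):
        for j in range(i + 1, L):
            block = rng.normal(0.0, scale, size=(q, q))
            J[i, j] = block
            J[j, i] = block.T
    return PottsEnergy(h, J)


def make_random_dataset(rng, L, q, labels=(0, 1, 2), M=15, max_count=8):
    alphabet = Alphabet.generic(q)
    rounds = [
        SequenceRound(t, rng.integers(0, q, size=(M, L)).astype(np.uint8),
                      rng.integers(1, max_count + 1, size=M))
        for t in labels
    ]
    return ScreeningDataset(rounds, alphabet)


@pytest.fixture
def random_energy():
    return make_random_energy


@pytest.fixture
def random_dataset():
    return make_random_dataset
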