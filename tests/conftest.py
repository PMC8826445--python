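import numpy as np
import pytest

from motifdecon.constants import AA_INDEX, CORE_LENGTH, UNIFORM_BACKGROUND
from motifdecon.predictor import AlleleModel


@pytest.fixture
def zero_model():
    return AlleleModel("HLA-A*01:01", np.zeros((CORE_LENGTH, 20)))


@pytest.fixture
def ala_model():
    """weights[i][A] = 1 at every position, else 0: counts alanines."""
    w = np.zeros((CORE_LENGTH, 20))
    w[:, AA_INDEX["A"]] = 1.0
    return AlleleModel("HLA-A*02:01", w, UNIFORM_BACKGROUND.copy())


def brute_force_score(model, peptide):
    """Independent all-window enumeration oracle for PSSM scoring."""
    best, best_off = None, None
    for off in range(len(peptide) - CORE_LENGTH + 1):
        s = sum(
            model.weights[i, AA_INDEX[peptide[off + i]]] for i in range(CORE_LENGTH)
        )
        if best is None or s > best:
            best, best_off = s, off
    return best, peptide[best_off : best_off + CORE_LENGTH], best_off


def random_model(rng, allele="HLA-X*99:99"):
    return AlleleModel(allele, rng.normal(size=(CORE_LENGTH, 20)))


def random_peptide(rng, length):
    from motifdecon.constants import AMINO_ACIDS

    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
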