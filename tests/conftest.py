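import numpy as np
import pytest

from fibroin.architecture import segment
from fibroin.gene_model import extract_cds
from fibroin.synthetic import FibroinSpec, generate

SEED = 20240001


@pytest.fixture(scope="session")
def ground_truth():
    """Default synthetic fibroin gene (mutation rate 0): planted truth for round trips."""
    return generate(FibroinSpec(seed=SEED))


@pytest.fixture(scope="session")
def gene_structure(ground_truth):
    return ground_truth.gene_structure()


@pytest.fixture(scope="session")
def cds(gene_structure):
    return extract_cds(gene_structure)


@pytest.fixture(scope="session")
def architecture_result(ground_truth):
    return segment(ground_truth.protein)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
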