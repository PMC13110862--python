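import numpy as np
import pytest

from pfosber.matrix import ExpressionMatrix
from pfosber.synthetic import SyntheticDesign, generate_expression_matrix

DOSES = np.array([0.0, 10.0, 100.0, 1000.0])


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(n_genes=40, responder_fraction=0.25, noise_sd=0.2, seed=7)


@pytest.fixture(scope="session")
def small_matrix(small_design):
    mat, truths = generate_expression_matrix(small_design)
    return mat, truths


@pytest.fixture()
def doses16():
    """Dose vector of the standard 4-concentration × 4-replicate design."""
    return np.repeat(DOSES, 4)


@pytest.fixture()
def flat_matrix():
    rng = np.random.default_rng(5)
    conc = np.repeat(DOSES, 4)
    values = 8.0 + rng.normal(0, 0.2, size=(20, conc.size))
    return ExpressionMatrix([f"g{i}" for i in range(20)], values, conc)
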