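from pathlib import Path

import numpy as np
import pytest

from mspcd.dataio import AssociationMatrix
from mspcd.synthetic import SyntheticConfig, generate_dataset, generate_worked_example

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def worked_example():
    return generate_worked_example()


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced planted-block dataset for fast end-to-end tests."""
    return generate_dataset(
        SyntheticConfig(n_circ=60, n_disease=16, n_blocks=4, seq_len=40, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_association(rng, n_rows=6, n_cols=5, p=0.4):
    """Random binary table, regenerated until it has at least one 1."""
    while True:
        values = (rng.random((n_rows, n_cols)) < p).astype(int)
        if values.sum():
            break
    return AssociationMatrix(
        values,
        [f"r{i}" for i in range(n_rows)],
        [f"c{j}" for j in range(n_cols)],
    )
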