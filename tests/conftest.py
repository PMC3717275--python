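import numpy as np
import pytest

from lctgsa import Phenotype, center_columns


@pytest.fixture
def rng():
    return np.random.default_rng(20130212)


@pytest.fixture
def frozen_10x4():
    """A fixed 10-sample x 4-gene matrix used by several reference-formula
    oracles (drawn once from a seeded generator and frozen here)."""
    return np.array(
        [
            [0.3457, -0.5212, 1.0031, -0.2829],
            [0.8216, 0.0917, -0.6419, 1.3925],
            [-1.0070, 0.6252, 0.2269, -0.4512],
            [0.5689, -1.2354, 0.4104, 0.8001],
            [-0.2915, 0.4436, -1.1120, 0.1437],
            [1.2030, -0.8095, 0.5513, -0.9428],
            [-0.7534, 1.0662, -0.3199, 0.5310],
            [0.1122, -0.3508, 0.9076, -1.2043],
            [-1.3348, 0.7821, -0.6632, 0.3514],
            [0.6390, -0.0919, 0.2477, 0.7125],
        ]
    )


@pytest.fixture
def centered_10x4(frozen_10x4):
    return center_columns(frozen_10x4, genes_in_rows=False)


@pytest.fixture
def frozen_phenotype():
    return Phenotype([0.91, -0.44, 1.52, 0.07, -1.13, 0.66, -0.25, 1.08, -0.87, 0.31])
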