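import numpy as np
import pytest

from blocktest.genotypes import GenotypeBlock, code_genotypes
from blocktest.simulate import SimSetting, simulate_block_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_block():
    """Deterministic 6-subject, 3-SNP block covering all genotype states."""
    g = np.array(
        [
            [0, 2, 1],
            [1, 2, 0],
            [2, 1, 0],
            [0, 1, 1],
            [1, 0, 2],
            [2, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeBlock(g, ["rs1", "rs2", "rs3"])


@pytest.fixture
def null_cohort(rng):
    """Simulated 5-SNP null cohort: genotypes + unrelated 0/1 phenotype."""
    setting = SimSetting(m=5, rho=0.5, raf=0.3, k=0, n=300)
    block = simulate_block_genotypes(setting, 600, rng)
    y = np.concatenate([np.ones(300, dtype=np.int8), np.zeros(300, dtype=np.int8)])
    rng.shuffle(y)
    return block, code_genotypes(block), y
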