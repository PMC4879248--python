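import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from episwarm import LabeledGenotypes, SNPPattern, SimulationSpec, simulate_case_control
from episwarm.simulate import PlantedPattern


@pytest.fixture(scope="session")
def planted_pair() -> SNPPattern:
    return SNPPattern([(1, 3), (3, 1)])


@pytest.fixture(scope="session")
def planted_data(planted_pair):
    """600 samples, 10 SNPs, one strong planted pair (case 0.35 vs control 0.10)."""
    spec = SimulationSpec(
        m_case=300,
        m_control=300,
        n_snps=10,
        planted=[PlantedPattern(planted_pair, 0.35, 0.10)],
        seed=11,
    )
    return simulate_case_control(spec)


@pytest.fixture()
def tiny_data():
    """Hand-written 6-sample, 4-SNP dataset for exact counting tests."""
    genotypes = np.array(
        [
            [1, 3, 2, 1],
            [2, 3, 1, 1],
            [1, 1, 1, 2],
            [3, 3, 2, 1],
            [2, 2, 3, 3],
            [1, 3, 1, 1],
        ],
        dtype=np.int8,
    )
    labels = ["case", "case", "case", "control", "control", "control"]
    return LabeledGenotypes(genotypes, labels, snp_ids=["rsA", "rsB", "rsC", "rsD"])
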