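import numpy as np
import pytest

from motifbench.motifs import PWM, MotifMetadata
from motifbench.pipeline import CompareParams, compare_study
from motifbench.synthetic_data import SimConfig, generate_study


def one_hot_pwm(site: str, name: str = "onehot", **meta) -> PWM:
    """PWM that puts probability 1 on each base of ``site``."""
    idx = ["ACGT".index(b) for b in site]
    matrix = np.zeros((len(site), 4))
    matrix[np.arange(len(site)), idx] = 1.0
    return PWM(name=name, matrix=matrix, metadata=MotifMetadata(**meta))


def random_pwm(width: int, seed: int, name: str = "rand") -> PWM:
    gen = np.random.default_rng(seed)
    matrix = gen.dirichlet(np.ones(4), size=width)
    return PWM(name=name, matrix=matrix)


@pytest.fixture
def make_one_hot():
    return one_hot_pwm


@pytest.fixture
def make_random_pwm():
    return random_pwm


TINY_CFG = SimConfig(
    n_proteins=2,
    n_ere_classes=3,
    ere_copies_per_class=8,
    ere_length=120,
    genome_length=120_000,
    motif_width=8,
    true_site_pool_size=40,
    peaks_per_dataset=30,
    seed=5,
)


@pytest.fixture(scope="session")
def tiny_cfg():
    return TINY_CFG


@pytest.fixture(scope="session")
def tiny_study():
    return generate_study(TINY_CFG)


@pytest.fixture(scope="session")
def default_study():
    """Full-size synthetic study at the default conditions (seed 11)."""
    return generate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_report(default_study):
    """Full pipeline output on the default study, shared across tests."""
    return compare_study(default_study, CompareParams(seed=11))
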