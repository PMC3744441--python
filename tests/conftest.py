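import numpy as np
import pytest

from tada.bayes import Hyperparameters
from tada.gene_model import GeneRecord, StudyDesign
from tada.simulate import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def asd_design() -> StudyDesign:
    """Sample sizes of the combined ASD dataset (trios + case/control)."""
    return StudyDesign(n_trios=932, n_cases=935, n_controls=870, categories=("LoF",))


@pytest.fixture(scope="session")
def trio_design() -> StudyDesign:
    return StudyDesign(n_trios=1000, categories=("LoF",))


@pytest.fixture(scope="session")
def default_hyper() -> Hyperparameters:
    return Hyperparameters()


@pytest.fixture(scope="session")
def null_genome():
    """A small all-null genome (no risk genes), one category."""
    cfg = SimConfig(m=2000, k=0, design=StudyDesign(n_trios=1000, categories=("LoF",)))
    return simulate_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def risk_genome():
    """A small genome with planted risk genes and case-control arms."""
    design = StudyDesign(n_trios=1000, n_cases=1000, n_controls=1000, categories=("LoF",))
    cfg = SimConfig(m=3000, k=200, design=design)
    return simulate_genome(cfg, seed=12)


def make_record(gene="G", dn=0, trans=0, nontrans=0, case=0, ctrl=0, mu=1e-6, cat="LoF"):
    return GeneRecord(
        gene_id=gene,
        mu={cat: mu},
        x_dn={cat: dn},
        x_t={cat: trans},
        x_nt={cat: nontrans},
        x_case={cat: case},
        x_ctrl={cat: ctrl},
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
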