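import numpy as np
import pandas as pd
import pytest

from misa.datasets import GeneticModel, StudyDataset, build_design_matrix
from misa.evidence import Priors
from misa.simulate import SimulationConfig, simulate_study


def make_dataset(n=60, s=4, seed=0, maf=0.3):
    """Tiny hand-rolled dataset (independent SNPs in HWE, no effects)."""
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, maf, size=(n, s)).astype(float)
    cov = pd.DataFrame(
        {
            "age": rng.normal(55, 8, size=n).round(1),
            "batch": rng.choice(["b1", "b2"], size=n),
            "gc50pct": rng.uniform(0.8, 0.99, size=n).round(3),
        }
    )
    info = pd.DataFrame(
        {"snp_id": [f"rs{j}" for j in range(s)], "gene": [f"G{j % 2}" for j in range(s)]}
    )
    status = rng.integers(0, 2, size=n)
    return StudyDataset(genotypes=geno, case_status=status, covariates=cov, snp_info=info)


@pytest.fixture
def tiny_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def small_study():
    """Simulated 6-SNP case-control study with one causal log-additive SNP."""
    cfg = SimulationConfig(
        n_snps=6,
        n_cases=150,
        n_controls=250,
        block_size=3,
        causal=[(0, GeneticModel.LOG_ADDITIVE, 1.8)],
        missing_rate=0.0,
        seed=7,
    )
    ds, truth = simulate_study(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def priors():
    return Priors()


@pytest.fixture(scope="session")
def small_design(small_study):
    return build_design_matrix(small_study[0])
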