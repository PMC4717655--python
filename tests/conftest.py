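import numpy as np
import pytest

from polyrisk.data import GenotypeMatrix, PhasedHaplotypes, Phenotype, VariantTable
from polyrisk.simulate import BlockModel, CausalUnit, RiskModel, simulate_cohort, simulate_pool


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_variants():
    return VariantTable(
        ids=[f"rs{i}" for i in range(1, 5)],
        chrom=["1", "1", "2", "2"],
        pos=[100, 200, 300, 400],
        allele1=list("AACG"),
        allele2=list("GGTA"),
    )


def random_dataset(rng, n=60, m=8, missing_rate=0.1):
    """Unstructured genotypes + balanced phenotype for round-trip tests."""
    values = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing_rate
    values[mask] = -1
    status = np.array([1] * (n // 2) + [0] * (n - n // 2))
    variants = VariantTable(
        ids=[f"snp{j}" for j in range(m)],
        chrom=["1"] * m,
        pos=list(range(1000, 1000 + m)),
        allele1=["A"] * m,
        allele2=["G"] * m,
    )
    return GenotypeMatrix(values), variants, Phenotype(status)


@pytest.fixture
def null_cohort():
    """No causal effects: phenotype independent of genotype (n=200, 30 SNPs)."""
    block = BlockModel(n_blocks=6, block_length=5, founders_per_block=4)
    pool = simulate_pool(block, 400, seed=11)
    model = RiskModel([], prevalence=0.5)
    return simulate_cohort(pool, model, 100, 100, seed=12)


@pytest.fixture
def signal_cohort():
    """One additive causal SNP, per-allele OR 2, balanced cohort of 1000."""
    block = BlockModel(n_blocks=4, block_length=5, founders_per_block=4)
    pool = simulate_pool(block, 500, seed=21)
    model = RiskModel(
        [CausalUnit(effect=np.log(2.0), variant=7)], prevalence=0.5
    )
    return simulate_cohort(pool, model, 500, 500, seed=22)
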