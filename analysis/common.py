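"""Shared study configuration for the analysis scripts.

One synthetic case/control cohort is used throughout: 10 LD blocks of 5
SNPs (4 founder haplotypes each, recombination 0.5 between blocks), one
additive causal SNP (per-allele OR 2) and one additive causal 3-SNP
window haplotype (per-copy OR 2), prevalence 10 %, 300 cases / 300
controls.  Every script regenerates it deterministically from the same
seed, so the scripts can be run independently and in any order.
"""

from pathlib import Path

import numpy as np

from polyrisk.cli import stage_seed
from polyrisk.simulate import (
    BlockModel,
    CausalUnit,
    RiskModel,
    simulate_cohort,
    simulate_pool,
)

SEED = 20260928

BLOCK_MODEL = BlockModel(
    n_blocks=10, block_length=5, founders_per_block=4,
    recombination_rate_between_blocks=0.5,
)

CAUSAL_SNP = 12  # inside block 3
CAUSAL_WINDOW = (30, 3)  # first three SNPs of block 7

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def study_pool():
    return simulate_pool(BLOCK_MODEL, 800, seed=stage_seed(SEED, "pool"))


def study_cohort():
    """The analysis cohort: phased truth, genotypes, phenotype, truth record."""
    pool = study_pool()
    window = pool[:, CAUSAL_WINDOW[0] : CAUSAL_WINDOW[0] + CAUSAL_WINDOW[1]]
    patterns, counts = np.unique(window, axis=0, return_counts=True)
    pattern = tuple(
        int(v) for v in patterns[np.argmin(np.abs(counts / counts.sum() - 0.3))]
    )
    risk = RiskModel(
        [
            CausalUnit(effect=np.log(2.0), variant=CAUSAL_SNP),
            CausalUnit(effect=np.log(2.0), window=CAUSAL_WINDOW, pattern=pattern),
        ],
        prevalence=0.1,
    )
    haps, genos, phen, truth = simulate_cohort(
        pool, risk, 300, 300, seed=stage_seed(SEED, "cohort")
    )
    truth["causal_pattern"] = pattern
    return haps, genos, phen, truth
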