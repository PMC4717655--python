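"""Synthetic case/control GWAS cohorts with known phase, LD and risk model.

The generator emulates the structure the downstream pipeline needs from a
real chip-genotyped cohort: biallelic SNPs organised in LD blocks
(haplotype pools built from a small number of founder haplotypes per
block), phased haplotype truth, and a binary disease status drawn from a
logistic liability with chosen causal variants or causal window
haplotypes, per-unit log odds ratios, additive/dominant/recessive action
and a configurable population prevalence K.  Missing genotypes can be
masked in afterwards, optionally at different rates in cases and
controls.

Draws are fully determined by the seed.  Because the original study's
data are access-controlled, these cohorts are the package's test bed;
they deliberately omit population stratification, genotyping batch
effects and realistic recombination maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import MISSING, GenotypeMatrix, PhasedHaplotypes, Phenotype, VariantTable

Action = Literal["additive", "dominant", "recessive"]


@dataclass
class BlockModel:
    """Haplotype-block LD structure for the founder pool.

    Each block holds ``founders_per_block`` founder haplotypes of
    ``block_length`` SNPs; a pool haplotype picks one founder per block,
    carrying the founder index across block boundaries except with
    probability ``recombination_rate_between_blocks`` (within-block
    recombination is 0, so blocks are perfect LD units).
    """

    n_blocks: int = 10
    block_length: int = 5
    founders_per_block: int = 4
    founder_frequencies: Sequence[float] | None = None
    recombination_rate_between_blocks: float = 0.5

    def __post_init__(self) -> None:
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.recombination_rate_between_blocks <= 1.0:
            raise ValueError("recombination rate must be in [0, 1]")
        if self.founder_frequencies is None:
            self.founder_frequencies = tuple(
                np.full(self.founders_per_block, 1.0 / self.founders_per_block)
            )
        freqs = np.asarray(self.founder_frequencies, dtype=float)
        if len(freqs) != self.founders_per_block or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("founder frequencies must sum to 1 per block")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_length


@dataclass
class CausalUnit:
    """One causal term of the liability: a variant or a window haplotype.

    ``effect`` is the log odds ratio contributed per risk unit; ``action``
    maps the per-individual dose (0/1/2 risk units on the diplotype) to
    the multiplier: additive uses the dose itself, dominant adds the
    effect once if dose >= 1, recessive only at dose 2.
    """

    effect: float
    action: Action = "additive"
    variant: int | None = None
    window: tuple[int, int] | None = None  # (start, length)
    pattern: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")
        if (self.variant is None) == (self.window is None):
            raise ValueError("specify exactly one of variant / (window, pattern)")
        if self.window is not None and self.pattern is None:
            raise ValueError("a window causal unit needs a haplotype pattern")

    def dose_per_haplotype(self, haplotypes: np.ndarray) -> np.ndarray:
        """Risk-unit indicator per haplotype row (carries allele/pattern)."""
        if self.variant is not None:
            return haplotypes[:, self.variant].astype(np.int64)
        start, length = self.window
        block = haplotypes[:, start : start + length]
        return (block == np.asarray(self.pattern)).all(axis=1).astype(np.int64)


def _apply_action(dose: np.ndarray, action: Action) -> np.ndarray:
    if action == "additive":
        return dose
    if action == "dominant":
        return (dose >= 1).astype(np.int64)
    if action == "recessive":
        return (dose == 2).astype(np.int64)
    raise ValueError(f"unknown genetic action {action!r}")


@dataclass
class RiskModel:
    """Logistic disease model: P(case) = expit(intercept + sum of effects)."""

    causal_units: list[CausalUnit] = field(default_factory=list)
    prevalence: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")

    def liability(self, h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        """Genetic part of the log odds for each diplotype (no intercept)."""
        eta = np.zeros(h1.shape[0])
        for unit in self.causal_units:
            dose = unit.dose_per_haplotype(h1) + unit.dose_per_haplotype(h2)
            eta += unit.effect * _apply_action(dose, unit.action)
        return eta


def _default_variant_table(n_variants: int) -> VariantTable:
    ids = np.array([f"SNP{j + 1}" for j in range(n_variants)], dtype=object)
    chrom = np.array(["1"] * n_variants, dtype=object)
    pos = np.arange(1, n_variants + 1) * 1000
    a1 = np.array(["A"] * n_variants, dtype=object)
    a2 = np.array(["G"] * n_variants, dtype=object)
    return VariantTable(ids, chrom, pos, a1, a2)


def draw_founders(
    block_model: BlockModel, rng: np.random.Generator,
    maf_low: float = 0.05, maf_high: float = 0.5, rare_fraction: float = 0.0,
) -> list[np.ndarray]:
    """Draw founder haplotype alleles per block.

    Site allele-1 frequencies are Uniform(maf_low, maf_high); a
    ``rare_fraction`` of sites instead gets a frequency below 1 % to
    exercise the MAF filter.  Founder alleles at each site are Bernoulli
    draws at that frequency (frequencies are realised through the founder
    mix, so per-site sample MAFs scatter around the target).
    """
    founders = []
    for _ in range(block_model.n_blocks):
        freqs = rng.uniform(maf_low, maf_high, size=block_model.block_length)
        rare = rng.random(block_model.block_length) < rare_fraction
        freqs[rare] = rng.uniform(0.0, 0.01, size=int(rare.sum()))
        founders.append(
            (rng.random((block_model.founders_per_block, block_model.block_length))
             < freqs).astype(np.int8)
        )
    return founders


def simulate_pool(
    block_model: BlockModel, pool_size: int, seed: int,
    founders: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Draw a pool of haplotypes as mosaics of per-block founders.

    Returns an array of shape (pool_size, n_variants).  Deterministic for
    a given seed.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    rng = np.random.default_rng(seed)
    if founders is None:
        founders = draw_founders(block_model, rng)
    freqs = np.asarray(block_model.founder_frequencies, dtype=float)
    r = block_model.recombination_rate_between_blocks

    idx = np.empty((pool_size, block_model.n_blocks), dtype=np.int64)
    idx[:, 0] = rng.choice(block_model.founders_per_block, size=pool_size, p=freqs)
    for b in range(1, block_model.n_blocks):
        recomb = rng.random(pool_size) < r
        fresh = rng.choice(block_model.founders_per_block, size=pool_size, p=freqs)
        idx[:, b] = np.where(recomb, fresh, idx[:, b - 1])

    pool = np.empty((pool_size, block_model.n_variants), dtype=np.int8)
    for b in range(block_model.n_blocks):
        cols = slice(b * block_model.block_length, (b + 1) * block_model.block_length)
        pool[:, cols] = founders[b][idx[:, b]]
    return pool


def calibrate_intercept(
    pool: np.ndarray, risk_model: RiskModel, rng: np.random.Generator,
    n_monte_carlo: int = 20000,
) -> float:
    """Root-find the intercept so mean disease probability hits prevalence K."""
    draws = rng.integers(0, pool.shape[0], size=(n_monte_carlo, 2))
    eta = risk_model.liability(pool[draws[:, 0]], pool[draws[:, 1]])
    K = risk_model.prevalence

    def gap(c: float) -> float:
        return float(expit(c + eta).mean() - K)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"prevalence {K} unattainable for the given effects"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate_cohort(
    pool: np.ndarray,
    risk_model: RiskModel,
    n_cases: int,
    n_controls: int,
    seed: int,
    variants: VariantTable | None = None,
) -> tuple[PhasedHaplotypes, GenotypeMatrix, Phenotype, dict]:
    """Sample a case/control cohort of exact sizes by rejection sampling.

    Each individual is two independent pool haplotypes (linkage
    equilibrium between the pair); disease status is Bernoulli at
    ``expit(intercept + liability)`` with the intercept calibrated to the
    model prevalence over the pool distribution.  Returns phased truth,
    genotypes (h1 + h2, no missingness), phenotype (cases first) and a
    truth record with per-individual liabilities and the calibrated
    intercept.
    """
    rng = np.random.default_rng(seed)
    intercept = calibrate_intercept(pool, risk_model, rng)

    need = {1: n_cases, 0: n_controls}
    got: dict[int, list[np.ndarray]] = {1: [], 0: []}
    liab: dict[int, list[float]] = {1: [], 0: []}
    batch = max(1024, 2 * (n_cases + n_controls))
    guard = 0
    while len(got[1]) < need[1] or len(got[0]) < need[0]:
        guard += 1
        if guard > 10000:
            raise RuntimeError("rejection sampling failed to fill the cohort")
        draws = rng.integers(0, pool.shape[0], size=(batch, 2))
        h1, h2 = pool[draws[:, 0]], pool[draws[:, 1]]
        eta = risk_model.liability(h1, h2)
        status = (rng.random(batch) < expit(intercept + eta)).astype(int)
        for s in (1, 0):
            take = np.flatnonzero(status == s)[: need[s] - len(got[s])]
            for t in take:
                got[s].append(np.stack([h1[t], h2[t]]))
                liab[s].append(float(eta[t]))

    pairs = got[1] + got[0]
    values = np.concatenate(pairs, axis=0)
    haplotypes = PhasedHaplotypes(values)
    phenotype = Phenotype(np.array([1] * n_cases + [0] * n_controls))
    truth = {
        "intercept": intercept,
        "liability": np.array(liab[1] + liab[0]),
        "risk_model": risk_model,
    }
    if variants is None:
        variants = _default_variant_table(pool.shape[1])
    truth["variants"] = variants
    return haplotypes, haplotypes.to_genotypes(), phenotype, truth


def mask_genotypes(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    rate_cases: float,
    rate_controls: float,
    seed: int,
) -> GenotypeMatrix:
    """Set entries to MISSING independently per cell at the class rate."""
    for name, rate in (("rate_cases", rate_cases), ("rate_controls", rate_controls)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = genotypes.values.copy()
    rates = np.where(phenotype.status == 1, rate_cases, rate_controls)
    mask = rng.random(values.shape) < rates[:, None]
    values[mask] = MISSING
    return GenotypeMatrix(values)
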