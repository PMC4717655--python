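"""Core in-memory containers for case/control GWAS data.

Genotypes are coded as copies of allele 1: 0 (homozygous allele 2),
1 (heterozygous), 2 (homozygous allele 1), with :data:`MISSING` (= -1)
for no-calls.  Phased haplotypes are binary allele sequences
(1 = allele 1, 0 = allele 2) stored two-per-individual in a fixed pair
order, so that ``h1 + h2`` reproduces the genotype at every non-missing
cell.

Phenotypes are stored with 1 = case (diseased) and 0 = control.  Some
model reports follow the opposite labelling convention in which "class 1"
denotes absence of disease; that convention is metadata on the report,
never on the stored phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

CASE: int = 1
CONTROL: int = 0


@dataclass
class VariantTable:
    """Per-variant metadata: identifier, chromosome, 1-based position, alleles.

    ``allele1`` is the counted allele of the genotype coding.
    """

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        n = len(self.ids)
        for name in ("chrom", "pos", "allele1", "allele2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"VariantTable field {name!r} has wrong length")
        if len(set(self.ids)) != n:
            raise ValueError("variant identifiers must be unique")
        if n and (self.pos < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")
        same = [i for i in range(n) if self.allele1[i] == self.allele2[i]]
        if same:
            raise ValueError(f"allele1 == allele2 at variant index {same[0]}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, index: np.ndarray) -> "VariantTable":
        index = np.asarray(index)
        return VariantTable(
            self.ids[index], self.chrom[index], self.pos[index],
            self.allele1[index], self.allele2[index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "chrom": self.chrom, "pos": self.pos,
             "allele1": self.allele1, "allele2": self.allele2}
        )


@dataclass
class Phenotype:
    """Disease status per individual: 1 = case, 0 = control."""

    status: np.ndarray
    #: Output-labelling convention used by model reports ("class 1" may mean
    #: healthy, as in stump-model tables); purely informational.
    class1_meaning: str = "case"

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.ndim != 1:
            raise ValueError("phenotype must be one-dimensional")
        bad = set(np.unique(self.status)) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"phenotype values must be 0/1, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.status)

    @property
    def n_cases(self) -> int:
        return int((self.status == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == CONTROL).sum())

    def require_both_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("need at least one case and one control")

    def subset(self, index: np.ndarray) -> "Phenotype":
        return Phenotype(self.status[np.asarray(index)], self.class1_meaning)


@dataclass
class GenotypeMatrix:
    """Individuals x variants matrix of allele-1 copy counts (0/1/2/MISSING)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be two-dimensional")
        ok = np.isin(self.values, (0, 1, 2, MISSING))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(f"invalid genotype {self.values[i, j]} at ({i}, {j})")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[:, np.asarray(index)])

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[np.asarray(index), :])


@dataclass
class PhasedHaplotypes:
    """Phased binary haplotypes, two consecutive rows per individual.

    Row ``2*i`` and ``2*i + 1`` are the ordered haplotype pair of
    individual ``i``.  Alleles are 1 (allele 1) / 0 (allele 2); the format
    carries no missingness.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("haplotypes must be two-dimensional")
        if self.values.shape[0] % 2 != 0:
            raise ValueError("haplotype rows must come in pairs (2 per individual)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def pair(self, individual: int) -> tuple[np.ndarray, np.ndarray]:
        return self.values[2 * individual], self.values[2 * individual + 1]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse each haplotype pair to its genotype (h1 + h2)."""
        return GenotypeMatrix(self.values[0::2] + self.values[1::2])

    def subset_individuals(self, index: np.ndarray) -> "PhasedHaplotypes":
        index = np.asarray(index)
        rows = np.empty(2 * len(index), dtype=np.int64)
        rows[0::2] = 2 * index
        rows[1::2] = 2 * index + 1
        return PhasedHaplotypes(self.values[rows])

    def subset_variants(self, index: np.ndarray) -> "PhasedHaplotypes":
        return PhasedHaplotypes(self.values[:, np.asarray(index)])


def check_phase_consistency(
    haplotypes: PhasedHaplotypes, genotypes: GenotypeMatrix
) -> None:
    """Assert h1 + h2 equals the genotype at every non-missing cell."""
    derived = haplotypes.values[0::2] + haplotypes.values[1::2]
    observed = genotypes.values
    mask = observed != MISSING
    if not (derived[mask] == observed[mask]).all():
        raise ValueError("haplotype pair sums disagree with genotypes")
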