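"""Readers and writers for PLINK text PED/MAP, Oxford HAPS/SAMPLE and TSV reports.

File positions stay 1-based as in the formats; everything in memory is
0-indexed.  The counted allele (allele 1) of each variant is the first
allele encountered in file order when reading PED, and is recorded in the
:class:`~polyrisk.data.VariantTable` so log-odds-ratio signs are
reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    CASE,
    CONTROL,
    MISSING,
    GenotypeMatrix,
    PhasedHaplotypes,
    Phenotype,
    VariantTable,
    check_phase_consistency,
)

logger = logging.getLogger(__name__)

_PED_PHENO = {"1": CONTROL, "2": CASE}  # 0 / -9 = missing


def read_map(map_path: str | Path) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ValueError(f"{map_path}: malformed MAP line {lineno}")
        chrom, snp = parts[0], parts[1]
        pos = int(parts[-1])
        rows.append((chrom, snp, pos))
    return pd.DataFrame(rows, columns=["chrom", "id", "pos"])


def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[GenotypeMatrix, VariantTable, Phenotype]:
    """Read a PLINK text PED/MAP pair into genotype-matrix form.

    PED phenotype column: 1 = control, 2 = case, 0 or -9 = missing
    (individuals with missing phenotype are dropped with a warning).
    "0 0" genotypes become :data:`MISSING`.  Genotypes are recoded as
    copies of allele 1, the first allele observed per variant in file
    order.
    """
    variants = read_map(map_path)
    n_var = len(variants)
    allele1: list[str | None] = [None] * n_var
    allele2: list[str | None] = [None] * n_var
    geno_rows: list[list[tuple[str, str] | None]] = []
    statuses: list[int] = []
    n_dropped = 0

    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_var:
            raise ValueError(
                f"{ped_path}: malformed PED line {lineno}: expected "
                f"{6 + 2 * n_var} fields, got {len(parts)}"
            )
        pheno = _PED_PHENO.get(parts[5])
        if pheno is None:
            n_dropped += 1
            continue
        alleles = parts[6:]
        row: list[tuple[str, str] | None] = []
        for j in range(n_var):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                if a != b:
                    raise ValueError(
                        f"{ped_path}: half-missing genotype at line {lineno}, "
                        f"variant {j + 1}"
                    )
                row.append(None)
                continue
            for al in (a, b):
                if allele1[j] is None:
                    allele1[j] = al
                elif allele2[j] is None and al != allele1[j]:
                    allele2[j] = al
                elif al not in (allele1[j], allele2[j]):
                    raise ValueError(
                        f"{ped_path}: more than two alleles for variant "
                        f"{j + 1} at line {lineno}"
                    )
            row.append((a, b))
        geno_rows.append(row)
        statuses.append(pheno)

    if n_dropped:
        logger.warning("dropped %d individuals with missing phenotype", n_dropped)

    # Monomorphic variants never reveal a second allele; use a placeholder.
    for j in range(n_var):
        if allele1[j] is None:
            allele1[j] = "0"  # never observed at all
            allele2[j] = "?"
        elif allele2[j] is None:
            allele2[j] = "?"

    values = np.full((len(geno_rows), n_var), MISSING, dtype=np.int8)
    for i, row in enumerate(geno_rows):
        for j, pair in enumerate(row):
            if pair is not None:
                values[i, j] = (pair[0] == allele1[j]) + (pair[1] == allele1[j])

    table = VariantTable(
        variants["id"].to_numpy(), variants["chrom"].to_numpy(),
        variants["pos"].to_numpy(), np.array(allele1, dtype=object),
        np.array(allele2, dtype=object),
    )
    return GenotypeMatrix(values), table, Phenotype(np.array(statuses))


def write_ped_map(
    genotypes: GenotypeMatrix,
    variants: VariantTable,
    phenotype: Phenotype,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Write genotypes to a PLINK text PED/MAP pair."""
    with open(map_path, "w") as fh:
        for j in range(len(variants)):
            fh.write(
                f"{variants.chrom[j]}\t{variants.ids[j]}\t0\t{variants.pos[j]}\n"
            )
    code = {2: "{a} {a}", 1: "{a} {b}", 0: "{b} {b}"}
    with open(ped_path, "w") as fh:
        for i in range(genotypes.n_individuals):
            pheno = "2" if phenotype.status[i] == CASE else "1"
            fields = [f"FAM{i + 1}", f"IND{i + 1}", "0", "0", "0", pheno]
            for j in range(genotypes.n_variants):
                g = int(genotypes.values[i, j])
                if g == MISSING:
                    fields.append("0 0")
                else:
                    fields.append(
                        code[g].format(a=variants.allele1[j], b=variants.allele2[j])
                    )
            fh.write(" ".join(fields) + "\n")


def read_haps_sample(
    haps_path: str | Path, sample_path: str | Path
) -> tuple[PhasedHaplotypes, VariantTable, Phenotype]:
    """Read Oxford HAPS/SAMPLE phased haplotypes (SHAPEIT-style output).

    HAPS rows are variants (chrom, id, pos, allele1, allele2 then two 0/1
    columns per individual, 1 meaning allele 1).  SAMPLE carries the
    binary phenotype in a ``pheno`` column (1 = control, 2 = case, PLINK
    convention) after the two header lines.
    """
    chroms, ids, poss, a1s, a2s, columns = [], [], [], [], [], []
    n_alleles: int | None = None
    for lineno, line in enumerate(Path(haps_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"{haps_path}: malformed HAPS line {lineno}")
        alleles = parts[5:]
        if n_alleles is None:
            n_alleles = len(alleles)
            if n_alleles % 2 != 0:
                raise ValueError(
                    f"{haps_path}: odd number of haplotype columns ({n_alleles})"
                )
        elif len(alleles) != n_alleles:
            raise ValueError(f"{haps_path}: ragged HAPS line {lineno}")
        chroms.append(parts[0])
        ids.append(parts[1])
        poss.append(int(parts[2]))
        a1s.append(parts[3])
        a2s.append(parts[4])
        try:
            columns.append([int(x) for x in alleles])
        except ValueError as exc:
            raise ValueError(f"{haps_path}: non-binary allele, line {lineno}") from exc

    values = np.array(columns, dtype=np.int8).T  # (2n, m)
    table = VariantTable(
        np.array(ids, dtype=object), np.array(chroms, dtype=object),
        np.array(poss), np.array(a1s, dtype=object), np.array(a2s, dtype=object),
    )

    sample_lines = [
        ln for ln in Path(sample_path).read_text().splitlines() if ln.strip()
    ]
    header = sample_lines[0].split()
    body = sample_lines[2:]  # line 2 is the type row
    if "pheno" not in header:
        raise ValueError(f"{sample_path}: no 'pheno' column")
    col = header.index("pheno")
    statuses, keep = [], []
    for i, line in enumerate(body):
        pheno = _PED_PHENO.get(line.split()[col])
        if pheno is None:
            logger.warning("dropping individual %d with missing phenotype", i + 1)
            continue
        statuses.append(pheno)
        keep.append(i)
    if values.shape[0] != 2 * len(body):
        raise ValueError(
            f"{haps_path}: {values.shape[0]} haplotype columns do not match "
            f"{len(body)} sample rows"
        )
    haplotypes = PhasedHaplotypes(values).subset_individuals(np.array(keep, dtype=int))
    check_phase_consistency(haplotypes, haplotypes.to_genotypes())
    return haplotypes, table, Phenotype(np.array(statuses))


def write_haps_sample(
    haplotypes: PhasedHaplotypes,
    variants: VariantTable,
    phenotype: Phenotype,
    haps_path: str | Path,
    sample_path: str | Path,
) -> None:
    """Write phased haplotypes in Oxford HAPS/SAMPLE form."""
    with open(haps_path, "w") as fh:
        for j in range(len(variants)):
            col = " ".join(str(int(x)) for x in haplotypes.values[:, j])
            fh.write(
                f"{variants.chrom[j]} {variants.ids[j]} {variants.pos[j]} "
                f"{variants.allele1[j]} {variants.allele2[j]} {col}\n"
            )
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing pheno\n0 0 0 B\n")
        for i in range(haplotypes.n_individuals):
            pheno = "2" if phenotype.status[i] == CASE else "1"
            fh.write(f"FAM{i + 1} IND{i + 1} 0 {pheno}\n")


REPORT_FLOAT_FORMAT = "%.4f"


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write an evaluation report as TSV, floats at 4 decimals, stable order."""
    df = report.copy()
    sort_cols = [c for c in ("learner", "threshold") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=REPORT_FLOAT_FORMAT)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
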