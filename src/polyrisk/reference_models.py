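"""Published reference inputs used by worked examples and validation.

A 7-SNP decision-stump ensemble of the form produced by 10 rounds of
AdaBoost.M1 on a Type 1 diabetes case/control GWAS (class 1 = healthy),
together with the two-group haplotype counts of the standard worked
example for the mAssocTest_2G statistic.  Both are transcriptions of
printed tables and serve as fixed inputs: scoring the stump model on a
genotype vector and evaluating the statistic on the counts must
reproduce the published numbers exactly.
"""

from __future__ import annotations

import numpy as np

from .boosting import StumpEnsemble, StumpRule
from .data import MISSING, VariantTable
from .haplotype import GroupCounts

#: Group counts of the worked example: second-half haplotype counts for
#: the case-enriched group g1 (53 case / 38 control) and its complement
#: g2 (47 case / 62 control).
WORKED_EXAMPLE_GROUP_COUNTS = GroupCounts(53, 38, 47, 62)

#: First-half haplotype counts (length-3 windows, alleles 000..111) from
#: which the worked example builds its g1/g2 partition.
WORKED_EXAMPLE_WINDOW_COUNTS = {
    "case": dict(zip(
        [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
         (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)],
        [13, 8, 11, 9, 14, 17, 16, 12],
    )),
    "control": dict(zip(
        [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
         (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)],
        [12, 11, 19, 7, 16, 13, 2, 20],
    )),
}

# (chrom, pos, snp, allele1, allele2, [(weight, genotype set), ...]);
# two weights carry the full precision quoted with the published
# worked-example sum, the rest the table's 4-decimal print precision.
_T1D_STUMP_ROWS = [
    ("1", 77051324, "SNP_A-1827111", "A", "C", [(0.0801, {0, MISSING})]),
    ("6", 32444658, "SNP_A-1934589", "A", "G", [(0.2326, {0})]),
    ("6", 30135583, "SNP_A-2111335", "A", "G",
     [(0.2170542636, {0}), (0.0543, {1})]),
    ("6", 31395153, "SNP_A-2079423", "C", "T", [(0.1525, {0, 1})]),
    ("6", 30390814, "SNP_A-2222387", "A", "G", [(0.0672, {0, 1})]),
    ("6", 31112694, "SNP_A-4293786", "C", "T", [(0.0517, {0, 1})]),
    ("19", 39266932, "SNP_A-4281637", "A", "G", [(0.0904392765, {0, 1})]),
]


def t1d_stump_model() -> tuple[StumpEnsemble, VariantTable]:
    """The published 7-SNP stump model and its variant annotation.

    All rules vote class 1 (healthy).  The printed weights sum to ~0.946
    because of print rounding; the ensemble is the normalized
    representation, and scoring sums raw weights (never re-divides), as
    the published worked example requires.
    """
    rules = []
    for j, (_, _, _, _, _, weighted) in enumerate(_T1D_STUMP_ROWS):
        for weight, genotypes in weighted:
            rules.append(StumpRule(j, frozenset(genotypes), True, weight))
    ensemble = StumpEnsemble(rules, normalized=True)
    variants = VariantTable(
        ids=[r[2] for r in _T1D_STUMP_ROWS],
        chrom=[r[0] for r in _T1D_STUMP_ROWS],
        pos=[r[1] for r in _T1D_STUMP_ROWS],
        allele1=[r[3] for r in _T1D_STUMP_ROWS],
        allele2=[r[4] for r in _T1D_STUMP_ROWS],
    )
    return ensemble, variants


#: Genotype vector (in model row order) that fires exactly the two rules
#: of the published scoring decomposition: genotype 0 at SNP_A-2111335
#: and genotype 1 at SNP_A-4281637.
WORKED_EXAMPLE_GENOTYPES = np.array([2, 2, 0, MISSING, 2, 2, 1], dtype=np.int8)

#: The published class-1 (healthy) probability for that vector.
WORKED_EXAMPLE_P_HEALTHY = 0.3074935401
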