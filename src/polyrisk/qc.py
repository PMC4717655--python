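"""Per-SNP cleaning: Hardy-Weinberg, differential missingness, MAF.

A variant survives iff it is in Hardy-Weinberg equilibrium in the case
and control strata (chi-square test, exclusion when p < alpha in either
stratum by default, configurable to require failure in both), its
missingness does not differ between cases and controls (2x2 Pearson
chi-square), and its minor allele frequency is at least ``maf_min``.
Individuals are never removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import CASE, CONTROL, MISSING, GenotypeMatrix, Phenotype

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    hwe_alpha: float = 0.05
    missingness_alpha: float = 0.05
    maf_min: float = 0.01
    #: exclude when HWE fails in "either" stratum (strict) or only in "both"
    hwe_strata: Literal["either", "both"] = "either"

    def __post_init__(self) -> None:
        for name in ("hwe_alpha", "missingness_alpha", "maf_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


def hwe_chi2_test(n_hom2: int, n_het: int, n_hom1: int) -> float:
    """1-df chi-square goodness-of-fit to Hardy-Weinberg genotype proportions.

    Counts are genotype classes 0/1/2 (copies of allele 1).  Expected
    counts come from the estimated allele frequency; expected-zero cells
    contribute nothing (monomorphic sites give p = 1).
    """
    counts = np.array([n_hom2, n_het, n_hom1], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes to test")
    p1 = (2 * counts[2] + counts[1]) / (2 * n)
    expected = n * np.array([(1 - p1) ** 2, 2 * p1 * (1 - p1), p1**2])
    nonzero = expected > 0
    stat = float((((counts - expected) ** 2)[nonzero] / expected[nonzero]).sum())
    return float(chi2.sf(stat, df=1))


def differential_missingness_test(
    n_miss_case: int, n_case: int, n_miss_ctrl: int, n_ctrl: int
) -> float:
    """Pearson 1-df chi-square (no continuity correction) on the 2x2
    missing/observed x case/control table.  Empty margins give p = 1."""
    if not (0 <= n_miss_case <= n_case and 0 <= n_miss_ctrl <= n_ctrl):
        raise ValueError("missing counts must lie within totals")
    a, b = n_miss_case, n_case - n_miss_case
    c, d = n_miss_ctrl, n_ctrl - n_miss_ctrl
    n = a + b + c + d
    if a + c == 0 or b + d == 0:
        # nothing missing anywhere (or everything missing): rates are equal
        return 1.0
    if n == 0 or a + b == 0 or c + d == 0:
        logger.warning("empty phenotype-class margin in missingness test; p = 1")
        return 1.0
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(chi2.sf(stat, df=1))


def minor_allele_frequency(column: np.ndarray) -> float:
    """Allele-1 frequency over non-missing genotypes, folded to min(f, 1-f)."""
    column = np.asarray(column)
    obs = column[column != MISSING]
    if obs.size == 0:
        raise ValueError("all genotypes missing")
    f = float(obs.sum()) / (2 * obs.size)
    return min(f, 1.0 - f)


def apply_qc(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter variants by the three cleaning rules; individuals are kept.

    Returns the filtered matrix and a per-variant report with the test
    p-values, the MAF, the verdict and the failing rules.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    values = genotypes.values
    is_case = phenotype.status == CASE
    is_ctrl = phenotype.status == CONTROL
    rows = []
    for j in range(genotypes.n_variants):
        col = values[:, j]
        fails = []
        hwe_ps = {}
        for name, mask in (("cases", is_case), ("controls", is_ctrl)):
            sub = col[mask]
            sub = sub[sub != MISSING]
            if sub.size == 0:
                hwe_ps[name] = 1.0
                continue
            hwe_ps[name] = hwe_chi2_test(
                int((sub == 0).sum()), int((sub == 1).sum()), int((sub == 2).sum())
            )
        hwe_fail_flags = [p < thresholds.hwe_alpha for p in hwe_ps.values()]
        hwe_fail = (
            any(hwe_fail_flags) if thresholds.hwe_strata == "either"
            else all(hwe_fail_flags)
        )
        if hwe_fail:
            fails.append("hwe")

        miss_p = differential_missingness_test(
            int((col[is_case] == MISSING).sum()), int(is_case.sum()),
            int((col[is_ctrl] == MISSING).sum()), int(is_ctrl.sum()),
        )
        if miss_p < thresholds.missingness_alpha:
            fails.append("missingness")

        if (col != MISSING).any():
            maf = minor_allele_frequency(col)
        else:
            maf = float("nan")
        if not maf >= thresholds.maf_min:  # NaN also fails
            fails.append("maf")

        rows.append(
            {
                "variant": j,
                "hwe_p_cases": hwe_ps["cases"],
                "hwe_p_controls": hwe_ps["controls"],
                "missingness_p": miss_p,
                "maf": maf,
                "verdict": "PASS" if not fails else "FAIL",
                "failed_rules": ",".join(fails),
            }
        )

    report = pd.DataFrame(
        rows,
        columns=[
            "variant", "hwe_p_cases", "hwe_p_controls", "missingness_p",
            "maf", "verdict", "failed_rules",
        ],
    )
    keep = report.index[report["verdict"] == "PASS"].to_numpy() if len(rows) else np.array([], dtype=int)
    kept = genotypes.subset_variants(keep) if len(rows) else GenotypeMatrix(values[:, :0])
    return kept, report
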