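"""Single-SNP association: Cochran-Armitage trend test and variant selection.

Selection (by p-value threshold or by top-K rank) is meant to run inside
each training fold so that no test-fold phenotype ever influences which
variants enter a model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .data import CASE, CONTROL, MISSING, GenotypeMatrix, Phenotype

#: The default grid of selection thresholds, strictly decreasing.
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    0.8, 0.5, 0.1, 0.05, 0.01, 0.001, 0.0001, 0.00001,
)

_SCORES = np.array([0.0, 1.0, 2.0])


@dataclass
class TrendTable:
    """Genotype counts by class: cases (c0, c1, c2), controls (k0, k1, k2)."""

    c0: int
    c1: int
    c2: int
    k0: int
    k1: int
    k2: int

    def __post_init__(self) -> None:
        counts = (self.c0, self.c1, self.c2, self.k0, self.k1, self.k2)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if sum(counts) == 0:
            raise ValueError("empty trend table")

    @property
    def cases(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.c2], dtype=float)

    @property
    def controls(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.k2], dtype=float)


def armitage_trend_test(table: TrendTable) -> tuple[float, float]:
    """Cochran-Armitage trend statistic with scores (0, 1, 2) and its 1-df p.

    Monomorphic (zero genotype variance) tables return (0, 1).  Raises if
    either phenotype class is empty.
    """
    c, k = table.cases, table.controls
    R, S = c.sum(), k.sum()
    if R == 0 or S == 0:
        raise ValueError("both phenotype classes must be present")
    n = c + k
    N = R + S
    T = float((_SCORES * (S * c - R * k)).sum())
    var = (R * S / N) * (
        N * float((_SCORES**2 * n).sum()) - float((_SCORES * n).sum()) ** 2
    )
    if var <= 0:
        return 0.0, 1.0
    stat = T * T / var
    return float(stat), float(chi2.sf(stat, df=1))


def trend_table_for_variant(
    column: np.ndarray, phenotype: Phenotype
) -> TrendTable:
    """Tabulate one genotype column by class, dropping missing calls."""
    col = np.asarray(column)
    is_case = phenotype.status == CASE
    counts = {}
    for prefix, mask in (("c", is_case), ("k", ~is_case)):
        sub = col[mask]
        sub = sub[sub != MISSING]
        for g in (0, 1, 2):
            counts[f"{prefix}{g}"] = int((sub == g).sum())
    return TrendTable(**counts)


def pvalues_for_all(
    genotypes: GenotypeMatrix, phenotype: Phenotype
) -> np.ndarray:
    """Per-variant trend-test p-values (complete cases per variant)."""
    phenotype.require_both_classes()
    return np.array(
        [
            armitage_trend_test(trend_table_for_variant(genotypes.values[:, j], phenotype))[1]
            for j in range(genotypes.n_variants)
        ]
    )


def select_by_threshold(p_values: np.ndarray, alpha: float) -> np.ndarray:
    """Indices with p < alpha, original variant order preserved."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    return np.flatnonzero(np.asarray(p_values) < alpha)


def select_top_k(p_values: np.ndarray, k: int = 100) -> np.ndarray:
    """Indices of the k smallest p-values, ties broken by variant order.

    The returned indices are in original variant order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(p_values)
    k = min(k, p.size)
    order = np.argsort(p, kind="stable")  # stable sort = file-order tie-break
    return np.sort(order[:k])
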