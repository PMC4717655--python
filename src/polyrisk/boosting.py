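"""AdaBoost.M1 over decision stumps on categorical genotype features.

A stump is a single rule on one variant: for a genotype subset S (any
non-empty proper subset of the values observed at that variant, with
missing as a first-class category) the stump votes one class inside S
and the other class outside.  The weak-learner search is exhaustive over
(variant, subset, vote class); with at most four categories per variant
this is at most 14 subsets x 2 votes each, found in O(n_individuals) per
variant from per-value class-weight sums.

The ensemble representation mirrors published stump-model tables: one
row per (variant, genotype set, vote), with normalized weights that sum
to 1, and a scoring rule that simply adds the weights of the rules whose
vote for the given genotype vector is "class 1" (healthy).  An
individual's probability of being healthy is that sum; rules whose vote
for the vector is the disease class contribute to the complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CASE, MISSING, GenotypeMatrix, Phenotype, VariantTable

logger = logging.getLogger(__name__)

#: Category order used for subset enumeration and reporting.
CATEGORY_ORDER = (0, 1, 2, MISSING)

_EPS_ERROR = 1e-10


@dataclass(frozen=True)
class StumpRule:
    """One decision rule: genotype of ``variant`` in ``genotypes`` -> vote.

    ``vote_healthy`` True means the rule votes class 1 (healthy, absence
    of disease) inside its genotype set; outside the set it votes the
    opposite class.
    """

    variant: int
    genotypes: frozenset[int]
    vote_healthy: bool
    weight: float

    def __post_init__(self) -> None:
        if not self.genotypes or not self.genotypes <= set(CATEGORY_ORDER):
            raise ValueError("genotype set must be a non-empty subset of {0,1,2,missing}")
        if self.weight < 0:
            raise ValueError("rule weight must be nonnegative")

    def fires(self, genotype_vector: np.ndarray) -> bool:
        return int(genotype_vector[self.variant]) in self.genotypes

    def votes_healthy(self, genotype_vector: np.ndarray) -> bool:
        return self.fires(genotype_vector) == self.vote_healthy


@dataclass
class StumpEnsemble:
    """A weighted list of stump rules; normalized weights sum to 1."""

    rules: list[StumpRule]
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.normalized and self.rules:
            total = sum(r.weight for r in self.rules)
            # Published tables round weights, so allow print-level slack.
            if not np.isclose(total, 1.0, atol=0.1):
                raise ValueError(
                    f"normalized ensemble weights sum to {total:.4f}, not 1"
                )

    def normalize(self) -> "StumpEnsemble":
        total = sum(r.weight for r in self.rules)
        if total <= 0:
            raise ValueError("cannot normalize an all-zero ensemble")
        return StumpEnsemble(
            [replace(r, weight=r.weight / total) for r in self.rules], True
        )


def _proper_subsets(values: Sequence[int]) -> list[frozenset[int]]:
    """Non-empty proper subsets, ordered by size then category order."""
    out = []
    for size in range(1, len(values)):
        for combo in combinations(values, size):
            out.append(frozenset(combo))
    return out


def _observed_values(column: np.ndarray) -> list[int]:
    present = set(int(v) for v in np.unique(column))
    return [v for v in CATEGORY_ORDER if v in present]


def fit_weighted_stump(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    instance_weights: np.ndarray,
) -> tuple[StumpRule, float]:
    """Exhaustive weighted-error minimization over all candidate stumps.

    Returns the best rule (weight field set to 0; ensemble weighting is
    the booster's job) and its weighted misclassification error.  Ties
    break toward the lower variant index, the smaller genotype set (then
    category order), and the healthy vote.  A single-class input yields a
    degenerate all-values... rather, the best constant rule with error 0.
    """
    w = np.asarray(instance_weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("instance weights must be nonnegative with positive sum")
    y_healthy = phenotype.status != CASE
    total_healthy = float(w[y_healthy].sum())
    total = float(w.sum())

    if y_healthy.all() or not y_healthy.any():
        # single-class input: a constant rule (full category set) is exact
        return StumpRule(0, frozenset(CATEGORY_ORDER), bool(y_healthy.all()), 0.0), 0.0

    best: tuple[float, int, int, int, int] | None = None  # error + tie keys
    best_rule: StumpRule | None = None
    subset_cache: dict[tuple[int, ...], list[frozenset[int]]] = {}

    for j in range(genotypes.n_variants):
        col = genotypes.values[:, j]
        values = _observed_values(col)
        if len(values) < 2:
            continue
        # per-value class-weight sums
        wh = {v: float(w[(col == v) & y_healthy].sum()) for v in values}
        wd = {v: float(w[(col == v) & ~y_healthy].sum()) for v in values}
        key = tuple(values)
        if key not in subset_cache:
            subset_cache[key] = _proper_subsets(values)
        for s_rank, subset in enumerate(subset_cache[key]):
            in_h = sum(wh[v] for v in subset)
            in_d = sum(wd[v] for v in subset)
            # vote healthy inside: wrong = diseased inside + healthy outside
            err_h = in_d + (total_healthy - in_h)
            for vote_healthy, err in ((True, err_h), (False, total - err_h)):
                cand = (err, j, len(subset), s_rank, 0 if vote_healthy else 1)
                if best is None or cand < best:
                    best = cand
                    best_rule = StumpRule(j, subset, vote_healthy, 0.0)

    if best_rule is None:
        # no variant with >= 2 observed values: constant vote by majority
        vote = total_healthy >= total / 2
        col_vals = _observed_values(genotypes.values[:, 0]) if genotypes.n_variants else [0]
        subset = frozenset({col_vals[0]})
        err = total - total_healthy if vote else total_healthy
        return StumpRule(0, subset, vote, 0.0), err / total
    return best_rule, best[0] / total


def train_adaboost_m1(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    n_iterations: int = 2500,
) -> StumpEnsemble:
    """Standard AdaBoost.M1 with exhaustive decision stumps.

    Round t fits a stump on the current instance weights; with weighted
    error e_t the rule gets ensemble weight alpha_t = ln((1 - e_t)/e_t)
    and correctly classified instances are downweighted by e_t/(1 - e_t)
    before renormalization.  Training stops early when e_t >= 0.5
    (the weak-learner guarantee fails) or e_t = 0 (the terminal perfect
    rule is still recorded).  The returned ensemble is normalized so rule
    weights sum to 1; raw alphas are kept on the side.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    phenotype.require_both_classes()
    n = genotypes.n_individuals
    D = np.full(n, 1.0 / n)
    y_healthy = phenotype.status != CASE

    rules: list[StumpRule] = []
    alphas: list[float] = []
    for t in range(n_iterations):
        rule, err = fit_weighted_stump(genotypes, phenotype, D)
        if err >= 0.5:
            logger.info("boosting stopped at round %d: weighted error %.3f >= 0.5",
                        t + 1, err)
            break
        alpha = float(np.log((1.0 - err) / max(err, _EPS_ERROR)))
        rules.append(rule)
        alphas.append(alpha)
        if err <= 0:
            logger.info("boosting stopped at round %d: perfect rule", t + 1)
            break
        col = genotypes.values[:, rule.variant]
        in_set = np.isin(col, list(rule.genotypes))
        pred_healthy = in_set == rule.vote_healthy
        correct = pred_healthy == y_healthy
        D = D * np.where(correct, err / (1.0 - err), 1.0)
        D = D / D.sum()

    if not rules:  # first stump already >= 0.5: fall back to the prior vote
        rule, err = fit_weighted_stump(genotypes, phenotype, D)
        rules, alphas = [rule], [1.0]
    total = sum(alphas)
    ensemble = StumpEnsemble(
        [replace(r, weight=a / total) for r, a in zip(rules, alphas)], True
    )
    ensemble.raw_alphas = list(alphas)  # unnormalized representation
    return ensemble


def score_ensemble(
    ensemble: StumpEnsemble, genotype_vector: np.ndarray
) -> float:
    """Probability of class 1 (healthy) under the additive table semantics.

    Each rule contributes its weight to the class it votes for the given
    vector (its own class inside its genotype set, the opposite class
    outside); p(healthy) is the summed weight of healthy votes.  With a
    normalized ensemble p(healthy) + p(diseased) = 1.  An ensemble
    explicitly flagged unnormalized is normalized on the fly with a
    warning.
    """
    if not ensemble.normalized:
        logger.warning("scoring an unnormalized ensemble: normalizing on the fly")
        ensemble = ensemble.normalize()
    vec = np.asarray(genotype_vector)
    return float(
        sum(r.weight for r in ensemble.rules if r.votes_healthy(vec))
    )


def score_ensemble_matrix(
    ensemble: StumpEnsemble, genotypes: GenotypeMatrix
) -> np.ndarray:
    """Vectorized p(healthy) for every individual."""
    if not ensemble.normalized:
        logger.warning("scoring an unnormalized ensemble: normalizing on the fly")
        ensemble = ensemble.normalize()
    out = np.zeros(genotypes.n_individuals)
    for r in ensemble.rules:
        col = genotypes.values[:, r.variant]
        fires = np.isin(col, list(r.genotypes))
        votes_healthy = fires if r.vote_healthy else ~fires
        out[votes_healthy] += r.weight
    return out


def _genotype_set_label(genotypes: frozenset[int]) -> str:
    parts = [
        "missing" if v == MISSING else str(v)
        for v in CATEGORY_ORDER
        if v in genotypes
    ]
    return "{" + ", ".join(parts) + "}"


def merge_rules(
    ensemble: StumpEnsemble, variants: VariantTable | None = None
) -> pd.DataFrame:
    """Collapse identical (variant, set, vote) rules into report rows.

    Weights of merged rules add, so the total weight is conserved.  With
    a variant table the rows are annotated with chromosome, position and
    alleles and sorted by (chromosome, position); otherwise by variant
    index.
    """
    agg: dict[tuple[int, frozenset[int], bool], float] = {}
    for r in ensemble.rules:
        key = (r.variant, r.genotypes, r.vote_healthy)
        agg[key] = agg.get(key, 0.0) + r.weight
    rows = []
    for (variant, genotypes, vote_healthy), weight in agg.items():
        row = {
            "variant": variant,
            "genotypes": _genotype_set_label(genotypes),
            "vote_class": 1 if vote_healthy else 0,
            "weight": weight,
        }
        if variants is not None:
            row.update(
                chrom=variants.chrom[variant], pos=int(variants.pos[variant]),
                snp=variants.ids[variant], allele1=variants.allele1[variant],
                allele2=variants.allele2[variant],
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if variants is not None and not df.empty:
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    elif not df.empty:
        df = df.sort_values("variant", kind="stable").reset_index(drop=True)
    return df
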