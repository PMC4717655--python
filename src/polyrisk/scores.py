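"""Simple genotype-based risk predictors.

Implements the classical single-score family and its Bayesian
equivalents:

* GRS: unweighted count of risk alleles over the selected variants,
  ``GRS(x) = sum_i x_i``.
* wGRS: the same sum weighted by per-variant allelic log odds ratios,
  ``wGRS(x) = sum_i w_i x_i`` with
  ``w_i = ln OR_i = ln [p(D|h=1)/p(D̄|h=1)] · [p(D̄|h=0)/p(D|h=0)]``.
* A one-covariate logistic link ``ln O(x) = a0 + a1 g(x)`` fitted on
  either score.
* A genotype naive Bayes classifier (conditionally independent SNPs
  given disease status, missing as its own category).
* An allelic naive Bayes classifier (the two alleles per SNP identically
  distributed and conditionally independent given status), which reduces
  to the logistic score model with slope 1 and intercept
  ``a0 = ln p(D)/(1-p(D)) + 2 sum_i ln[p(h_i=0|D)/p(h_i=0|D̄)]``;
  its log odds is ``a0 + sum_i w_i x_i``, so its ranking — and hence its
  AUC — coincides exactly with the wGRS built from the same weights.

Missing genotypes contribute 0 to GRS/wGRS (equivalent to imputing the
non-risk homozygote).  Conditional probabilities use add-1 smoothing and
allelic 2x2 tables use the Haldane-Anscombe 0.5 correction when any cell
is zero, so every weight is finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import expit

from .data import CASE, CONTROL, MISSING, GenotypeMatrix, Phenotype

logger = logging.getLogger(__name__)

_SLOPE_CLAMP = 25.0


def grs(genotypes: np.ndarray) -> np.ndarray:
    """Unweighted genetic risk score: sum of risk-allele counts.

    Accepts a vector (one individual) or a matrix (individuals x selected
    variants); MISSING contributes 0.
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, 0.0, g)
    return g.sum(axis=-1)


def wgrs(genotypes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted genetic risk score: sum of w_i * x_i, MISSING as 0.

    Summation is correctly rounded (math.fsum), so individuals whose
    scores are equal in real arithmetic get bit-identical doubles; this
    keeps the ranking — and hence the AUC — of the weighted score
    exactly equal to that of the allelic naive Bayes log odds built from
    the same weights.
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, 0.0, g)
    contrib = np.atleast_2d(g) * np.asarray(weights, dtype=float)
    out = np.array([math.fsum(row) for row in contrib])
    return out if g.ndim > 1 else out[0]


def allelic_log_or(a: float, b: float, c: float, d: float) -> float:
    """ln odds ratio of the allelic 2x2 table.

    ``a``/``b`` are case allele-1/allele-2 counts, ``c``/``d`` the control
    counts.  Adds 0.5 to every cell when any cell is zero (Haldane-
    Anscombe), so the result is always finite.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("allele counts must be nonnegative")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(np.log((a * d) / (b * c)))


def allelic_counts(column: np.ndarray, phenotype: Phenotype) -> tuple[int, int, int, int]:
    """Allele-1/allele-2 counts in cases and controls for one variant."""
    col = np.asarray(column)
    out = []
    for mask in (phenotype.status == CASE, phenotype.status == CONTROL):
        sub = col[mask]
        sub = sub[sub != MISSING]
        n1 = int(sub.sum())
        out.extend([n1, int(2 * sub.size - n1)])
    return tuple(out)  # (a, b, c, d)


def fit_score_weights(
    genotypes: GenotypeMatrix, phenotype: Phenotype
) -> np.ndarray:
    """Per-variant allelic ln OR weights learned from this (training) data."""
    phenotype.require_both_classes()
    return np.array(
        [
            allelic_log_or(*allelic_counts(genotypes.values[:, j], phenotype))
            for j in range(genotypes.n_variants)
        ]
    )


@dataclass
class LogisticScoreModel:
    """One-covariate logistic fit ln O = a0 + a1 * score."""

    alpha0: float
    alpha1: float
    score_kind: Literal["grs", "wgrs", "other"] = "other"

    def predict_log_odds(self, scores: np.ndarray) -> np.ndarray:
        return self.alpha0 + self.alpha1 * np.asarray(scores, dtype=float)

    def predict_proba(self, scores: np.ndarray) -> np.ndarray:
        return expit(self.predict_log_odds(scores))


def fit_score_logistic(
    scores: np.ndarray,
    phenotype: Phenotype,
    score_kind: Literal["grs", "wgrs", "other"] = "other",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticScoreModel:
    """Maximum-likelihood logistic regression of status on a single score.

    Newton-Raphson on (a0, a1); under (quasi-)separation the slope is
    clamped at +/-25 with a warning.
    """
    phenotype.require_both_classes()
    x = np.asarray(scores, dtype=float)
    y = phenotype.status.astype(float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    if x.std() == 0:
        # degenerate covariate: slope unidentifiable, keep 0
        p = y.mean()
        return LogisticScoreModel(float(np.log(p / (1 - p))), 0.0, score_kind)
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (y - p)
        w = p * (1 - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < tol:
            break
        if abs(beta[1]) > _SLOPE_CLAMP:
            logger.warning("separation detected; clamping logistic slope at %g",
                           _SLOPE_CLAMP)
            beta[1] = np.sign(beta[1]) * _SLOPE_CLAMP
            # refit intercept only at the clamped slope
            for _ in range(max_iter):
                p = expit(X @ beta)
                g0 = float((y - p).sum())
                h0 = float((p * (1 - p)).sum())
                if h0 == 0:
                    break
                beta[0] += g0 / h0
                if abs(g0 / h0) < tol:
                    break
            break
    return LogisticScoreModel(float(beta[0]), float(beta[1]), score_kind)


_NBC_CATEGORIES = (0, 1, 2, MISSING)


@dataclass
class NBCModel:
    """Genotype naive Bayes: class prior and per-SNP conditionals.

    Conditionals are over the four categories 0/1/2/missing with add-1
    smoothing; rows sum to 1 per class per variant.
    """

    prior_case: float
    #: arrays of shape (n_variants, 4) in category order (0, 1, 2, MISSING)
    cond_case: np.ndarray = field(repr=False)
    cond_control: np.ndarray = field(repr=False)

    def log_likelihood_ratio(self, genotypes: np.ndarray) -> np.ndarray:
        g = np.atleast_2d(np.asarray(genotypes))
        cat = np.select([g == 0, g == 1, g == 2], [0, 1, 2], default=3)
        idx = np.arange(g.shape[1])
        llr = (
            np.log(self.cond_case[idx, cat]) - np.log(self.cond_control[idx, cat])
        ).sum(axis=1)
        return llr

    def posterior(self, genotypes: np.ndarray) -> np.ndarray:
        """p(D | x), computed in log space."""
        prior_lo = np.log(self.prior_case) - np.log(1 - self.prior_case)
        out = expit(prior_lo + self.log_likelihood_ratio(genotypes))
        return out if np.asarray(genotypes).ndim > 1 else float(out[0])


def fit_nbc(genotypes: GenotypeMatrix, phenotype: Phenotype) -> NBCModel:
    phenotype.require_both_classes()
    conds = {}
    for cls, label in ((CASE, "case"), (CONTROL, "control")):
        sub = genotypes.values[phenotype.status == cls]
        counts = np.stack(
            [(sub == c).sum(axis=0) for c in _NBC_CATEGORIES], axis=1
        ).astype(float)
        counts += 1.0  # add-1 smoothing
        conds[label] = counts / counts.sum(axis=1, keepdims=True)
    prior = phenotype.n_cases / len(phenotype)
    return NBCModel(prior, conds["case"], conds["control"])


@dataclass
class ANBCModel:
    """Allelic naive Bayes: per-variant allelic conditionals, slope fixed at 1.

    ``alpha0`` follows the closed form of the logistic reduction; the log
    odds is ``alpha0 + sum_i w_i x_i`` with the allelic ln OR weights.
    """

    alpha0: float
    weights: np.ndarray
    p1_case: np.ndarray = field(repr=False)  # p(h=1 | D) per variant
    p1_control: np.ndarray = field(repr=False)

    def log_odds(self, genotypes: np.ndarray) -> np.ndarray:
        return self.alpha0 + wgrs(genotypes, self.weights)

    def predict_proba(self, genotypes: np.ndarray) -> np.ndarray:
        return expit(self.log_odds(genotypes))


def fit_anbc(genotypes: GenotypeMatrix, phenotype: Phenotype) -> ANBCModel:
    """Fit the allelic NBC with add-1 smoothing on allele counts."""
    phenotype.require_both_classes()
    p1_case = np.empty(genotypes.n_variants)
    p1_ctrl = np.empty(genotypes.n_variants)
    for j in range(genotypes.n_variants):
        a, b, c, d = allelic_counts(genotypes.values[:, j], phenotype)
        p1_case[j] = (a + 1.0) / (a + b + 2.0)
        p1_ctrl[j] = (c + 1.0) / (c + d + 2.0)
    weights = np.log(p1_case / (1 - p1_case)) - np.log(p1_ctrl / (1 - p1_ctrl))
    prior = phenotype.n_cases / len(phenotype)
    alpha0 = float(
        np.log(prior / (1 - prior))
        + 2 * np.log((1 - p1_case) / (1 - p1_ctrl)).sum()
    )
    return ANBCModel(alpha0, weights, p1_case, p1_ctrl)
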