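"""Metrics and validation protocols.

AUC is the Mann-Whitney rank statistic (ties count one half): the
probability that a random case outranks a random control.  Confusion
metrics use a 0.5 probability threshold.  Validation is stratified
10-fold cross-validation with all selection and fitting confined to the
training fold (the anti-leakage contract), or a stratified 50/50
holdout; fold-level AUC vectors can be compared with a Wilcoxon
signed-rank or a paired t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_rel, wilcoxon

from .data import CASE, GenotypeMatrix, Phenotype

FitScore = Callable[[GenotypeMatrix, Phenotype, GenotypeMatrix], np.ndarray]
"""Pipeline contract: fit on the training fold, score the test genotypes.

The callable receives only training-fold data for fitting, so no test
phenotype can leak into selection or weights.
"""


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC with cases (label 1) as positives; ties count 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == CASE
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, precision, sensitivity (= recall), specificity.

    Predicted case when score >= threshold.  A metric with an empty
    denominator is reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    is_case = labels == CASE
    if not is_case.any() or is_case.all():
        raise ValueError("confusion metrics need both classes")
    tp = int((pred & is_case).sum())
    fp = int((pred & ~is_case).sum())
    fn = int((~pred & is_case).sum())
    tn = int((~pred & ~is_case).sum())

    def ratio(num, den):
        return num / den if den else float("nan")

    return {
        "accuracy": (tp + tn) / len(labels),
        "precision": ratio(tp, tp + fp),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
    }


def metric_set(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    out = confusion_metrics(scores, labels)
    out["auc"] = auc(scores, labels)
    return out


@dataclass
class FoldPlan:
    """k disjoint, class-stratified folds of individual indices."""

    folds: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        flat = np.concatenate(self.folds) if self.folds else np.array([], dtype=int)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("folds must be disjoint")


def make_folds(phenotype: Phenotype, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified fold assignment: each class dealt round-robin after a
    seeded shuffle, so per-fold class ratios are within one individual of
    the global ratio."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (CASE, 1 - CASE):
        idx = np.flatnonzero(phenotype.status == cls)
        rng.shuffle(idx)
        for i, ind in enumerate(idx):
            folds[i % k].append(int(ind))
    return FoldPlan([np.sort(np.array(f, dtype=int)) for f in folds], seed)


def cross_validate(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    pipeline: FitScore,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[dict[str, float]], pd.DataFrame]:
    """k-fold cross-validation with in-fold fitting and selection.

    Returns the per-fold metric dicts and a summary frame with the
    median (the headline), mean, min and max of each metric.  A fold
    missing a class raises, naming the fold.
    """
    plan = make_folds(phenotype, k, seed)
    all_idx = np.arange(len(phenotype))
    per_fold = []
    for f, test_idx in enumerate(plan.folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_test = phenotype.subset(test_idx)
        y_train = phenotype.subset(train_idx)
        try:
            y_test.require_both_classes()
            y_train.require_both_classes()
        except ValueError as exc:
            raise ValueError(f"fold {f} lost a phenotype class") from exc
        test_scores = pipeline(
            genotypes.subset_individuals(train_idx), y_train,
            genotypes.subset_individuals(test_idx),
        )
        per_fold.append(metric_set(np.asarray(test_scores), y_test.status))

    frame = pd.DataFrame(per_fold)
    summary = frame.agg(["median", "mean", "min", "max"])
    return per_fold, summary


def holdout_split(
    phenotype: Phenotype, seed: int = 0, swap: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 50/50 split into (training, test) index arrays.

    With an odd class the extra individual lands in the test half.
    ``swap`` exchanges the halves (the model-reproducibility experiment).
    """
    rng = np.random.default_rng(seed)
    a_parts, b_parts = [], []
    for cls in (CASE, 1 - CASE):
        idx = np.flatnonzero(phenotype.status == cls)
        rng.shuffle(idx)
        half = len(idx) // 2
        a_parts.append(idx[:half])
        b_parts.append(idx[half:])
    train = np.sort(np.concatenate(a_parts))
    test = np.sort(np.concatenate(b_parts))
    return (test, train) if swap else (train, test)


def compare_folds(
    auc_a: np.ndarray, auc_b: np.ndarray, test: str = "wilcoxon_signed_rank"
) -> float:
    """Two-sided paired comparison of fold-wise AUC vectors."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equal-length vectors of at least 5 folds")
    if np.allclose(a, b):
        return 1.0
    if test == "wilcoxon_signed_rank":
        return float(wilcoxon(a, b, alternative="two-sided", method="exact").pvalue)
    if test == "paired_t":
        return float(ttest_rel(a, b).pvalue)
    raise ValueError(f"unknown test {test!r}")


def genotype_pipeline(
    learner_name: str,
    alpha: float | None = None,
    top_k: int | None = None,
    seed: int = 0,
    **hyper,
) -> FitScore:
    """Build a FitScore callable: in-fold trend-test selection + learner.

    Exactly one of ``alpha`` (p < alpha selection) or ``top_k`` (lowest-p
    rank selection) must be given.  With no variant selected the
    pipeline scores everyone 0.5.
    """
    from .association import pvalues_for_all, select_by_threshold, select_top_k
    from .learners import delegated_learner

    if (alpha is None) == (top_k is None):
        raise ValueError("give exactly one of alpha / top_k")

    def fit_score(
        train_g: GenotypeMatrix, train_y: Phenotype, test_g: GenotypeMatrix
    ) -> np.ndarray:
        p = pvalues_for_all(train_g, train_y)
        idx = (
            select_by_threshold(p, alpha) if alpha is not None
            else select_top_k(p, top_k)
        )
        if idx.size == 0:
            return np.full(test_g.n_individuals, 0.5)
        learner = delegated_learner(learner_name, seed=seed, **hyper)
        learner.fit(train_g.values[:, idx], train_y.status)
        return np.asarray(learner.predict_risk(test_g.values[:, idx]))

    return fit_score
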