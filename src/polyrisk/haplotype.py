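"""Haplotype-based risk prediction via two-group window statistics.

The pipeline runs in five steps on phased data:

1. split the training individuals 50/50 (seeded, stratified) into a
   group-construction half and a statistic/fit half;
2. for every sliding window (offset 1, lengths 1-5) build from the first
   half the case-enriched haplotype group g1 (strictly more frequent in
   cases) and its complement g2;
3. score each window on the *second* half with the two-group case/control
   statistic ``mAssocTest_2G = (n_cas_g1 - n_cont_g1)^2 / n_g1 +
   (n_cas_g2 - n_cont_g2)^2 / n_g2`` and keep windows with p < alpha
   (chi-square tail, 1 df by default — the df that reproduces the
   published worked example — 2 df available);
4. encode each second-half haplotype as a binary vector of window-group
   memberships and train a haplotype-risk learner, labelling both
   haplotypes of a case high-risk and both haplotypes of a control
   low-risk;
5. score test individuals: each of their two genome-wide haplotypes gets
   a risk probability, combined additively on the log-odds scale
   (or by max / min for dominant / recessive genetic action).

Haplotypes unseen in training are assigned to the group of their most
similar training haplotype under the length measure (longest run of
consecutive matching alleles), ties going to low-risk.

The transmission-based trio analogue ``mTDT_2G = (n_g1g2 - n_g2g1)^2 /
n_g`` is provided as a statistic only (no trio bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import chi2

from .data import CASE, GenotypeMatrix, PhasedHaplotypes, Phenotype
from .learners import Learner, delegated_learner

Hap = tuple[int, ...]

_P_CLAMP = 1e-12


@dataclass(frozen=True)
class Window:
    """A sliding window of ``length`` consecutive variants from ``start``."""

    start: int
    length: int

    def slice(self) -> slice:
        return slice(self.start, self.start + self.length)


def enumerate_windows(n_variants: int, length: int) -> list[Window]:
    """All windows of the given length with offset 1 (n - L + 1 of them)."""
    if not 1 <= length <= n_variants:
        raise ValueError(f"window length {length} not in [1, {n_variants}]")
    return [Window(s, length) for s in range(n_variants - length + 1)]


@dataclass
class HaplotypeGroups:
    """The g1/g2 partition of the haplotypes observed in one window.

    g1 holds the haplotypes strictly more frequent in cases than in
    controls; everything else observed (ties included) is g2.
    """

    g1: frozenset[Hap]
    g2: frozenset[Hap]
    case_counts: dict[Hap, int] = field(default_factory=dict)
    control_counts: dict[Hap, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.g1 & self.g2:
            raise ValueError("g1 and g2 must be disjoint")


@dataclass
class GroupCounts:
    """Haplotype counts by class and group on the statistic half."""

    n_cas_g1: int
    n_cont_g1: int
    n_cas_g2: int
    n_cont_g2: int

    def __post_init__(self) -> None:
        if min(self.n_cas_g1, self.n_cont_g1, self.n_cas_g2, self.n_cont_g2) < 0:
            raise ValueError("group counts must be nonnegative")

    @property
    def n_g1(self) -> int:
        return self.n_cas_g1 + self.n_cont_g1

    @property
    def n_g2(self) -> int:
        return self.n_cas_g2 + self.n_cont_g2


@dataclass
class TransmissionCounts:
    """Parental transmissions between groups for the trio statistic."""

    n_g1g2: int
    n_g2g1: int
    n_g: int

    def __post_init__(self) -> None:
        if min(self.n_g1g2, self.n_g2g1, self.n_g) < 0:
            raise ValueError("transmission counts must be nonnegative")
        if self.n_g1g2 + self.n_g2g1 > self.n_g:
            raise ValueError("transmissions exceed qualifying parental genotypes")


def m_tdt_2g(counts: TransmissionCounts) -> float:
    """Two-group multimarker TDT statistic (McNemar form)."""
    if counts.n_g == 0:
        raise ValueError("no qualifying parental genotypes")
    return (counts.n_g1g2 - counts.n_g2g1) ** 2 / counts.n_g


def m_assoc_test_2g(counts: GroupCounts, df: int = 1) -> tuple[float, float]:
    """Two-group case/control statistic and its chi-square tail p-value.

    A group with zero total contributes 0; both groups empty is an error.
    ``df`` defaults to 1, which reproduces the published worked example
    (p = 0.033175 at statistic 4.5368); 2 is also accepted.
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    if counts.n_g1 == 0 and counts.n_g2 == 0:
        raise ValueError("both haplotype groups are empty")
    stat = 0.0
    if counts.n_g1 > 0:
        stat += (counts.n_cas_g1 - counts.n_cont_g1) ** 2 / counts.n_g1
    if counts.n_g2 > 0:
        stat += (counts.n_cas_g2 - counts.n_cont_g2) ** 2 / counts.n_g2
    return float(stat), float(chi2.sf(stat, df=df))


def window_haplotype_counts(
    haplotypes: PhasedHaplotypes, phenotype: Phenotype, window: Window
) -> tuple[dict[Hap, int], dict[Hap, int]]:
    """Case and control haplotype counts within one window (2 per person)."""
    sub = haplotypes.values[:, window.slice()]
    status = np.repeat(phenotype.status, 2)
    case_counts: dict[Hap, int] = {}
    control_counts: dict[Hap, int] = {}
    for row, s in zip(sub, status):
        key = tuple(int(v) for v in row)
        target = case_counts if s == CASE else control_counts
        target[key] = target.get(key, 0) + 1
    return case_counts, control_counts


def build_groups(
    case_counts: dict[Hap, int], control_counts: dict[Hap, int]
) -> HaplotypeGroups:
    """Partition observed haplotypes: case count > control count -> g1."""
    observed = set(case_counts) | set(control_counts)
    g1 = frozenset(
        h for h in observed if case_counts.get(h, 0) > control_counts.get(h, 0)
    )
    g2 = frozenset(observed - g1)
    return HaplotypeGroups(g1, g2, dict(case_counts), dict(control_counts))


def length_measure(h_a, h_b) -> int:
    """Longest run of consecutive positions at which the alleles agree."""
    a = np.asarray(h_a)
    b = np.asarray(h_b)
    if a.shape != b.shape:
        raise ValueError("haplotypes must have equal length")
    best = run = 0
    for match in a == b:
        run = run + 1 if match else 0
        best = max(best, run)
    return int(best)


def assign_group(haplotype, groups: HaplotypeGroups) -> int:
    """1 if the haplotype sides with g1 (high risk), else 0.

    Exact members keep their group; unseen haplotypes take the group of
    the most similar training haplotype under the length measure, with
    ties across groups resolved to low risk (0).
    """
    key = tuple(int(v) for v in np.asarray(haplotype))
    if key in groups.g1:
        return 1
    if key in groups.g2:
        return 0
    best_g1 = max((length_measure(key, h) for h in groups.g1), default=-1)
    best_g2 = max((length_measure(key, h) for h in groups.g2), default=-1)
    return 1 if best_g1 > best_g2 else 0


def encode_features(
    haplotype: np.ndarray,
    windows: list[Window],
    groups_per_window: list[HaplotypeGroups],
) -> np.ndarray:
    """Binary membership vector (one bit per selected window)."""
    return np.array(
        [
            assign_group(np.asarray(haplotype)[w.slice()], g)
            for w, g in zip(windows, groups_per_window)
        ],
        dtype=np.int8,
    )


def _encode_all(
    haplotypes: PhasedHaplotypes,
    windows: list[Window],
    groups_per_window: list[HaplotypeGroups],
) -> np.ndarray:
    """Feature matrix for every haplotype row (2 per individual)."""
    n_rows = haplotypes.values.shape[0]
    X = np.empty((n_rows, len(windows)), dtype=np.int8)
    for i in range(n_rows):
        X[i] = encode_features(haplotypes.values[i], windows, groups_per_window)
    return X


def train_haplotype_predictor(
    features: np.ndarray, haplotype_labels: np.ndarray, learner: Learner
) -> Learner:
    """Fit the haplotype-risk learner on per-haplotype binary features.

    Each training individual contributes exactly two labelled haplotype
    instances (both high-risk for a case, both low-risk for a control).
    """
    return learner.fit(np.asarray(features), np.asarray(haplotype_labels))


def combine_risks(p_h1, p_h2, genetic_model: str = "additive"):
    """Combine the two genome-wide haplotype risks into individual risk.

    additive: multiplicative on the odds — sigmoid(logit(p1) + logit(p2));
    dominant: max; recessive: min.  Probabilities are clamped away from
    0/1 before the logit.
    """
    p1 = np.clip(np.asarray(p_h1, dtype=float), _P_CLAMP, 1 - _P_CLAMP)
    p2 = np.clip(np.asarray(p_h2, dtype=float), _P_CLAMP, 1 - _P_CLAMP)
    if genetic_model == "additive":
        return expit(logit(p1) + logit(p2))
    if genetic_model == "dominant":
        return np.maximum(p1, p2)
    if genetic_model == "recessive":
        return np.minimum(p1, p2)
    raise ValueError(f"unknown genetic model {genetic_model!r}")


def _stratified_half_split(
    phenotype: Phenotype, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    first, second = [], []
    for cls in (CASE, 1 - CASE):
        idx = np.flatnonzero(phenotype.status == cls)
        rng.shuffle(idx)
        half = len(idx) // 2
        first.append(idx[:half])
        second.append(idx[half:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


@dataclass
class HaplotypePipelineResult:
    """Scores and bookkeeping from one haplotype-pipeline run."""

    test_risk: np.ndarray
    windows: list[Window]
    selected: list[int]
    window_stats: pd.DataFrame
    groups: list[HaplotypeGroups]
    learner: Learner


def run_haplotype_pipeline(
    train_haplotypes: PhasedHaplotypes,
    train_phenotype: Phenotype,
    test_haplotypes: PhasedHaplotypes,
    length: int,
    alpha: float,
    learner: str | Learner = "nbc",
    genetic_model: str = "additive",
    seed: int = 0,
    df: int = 1,
) -> HaplotypePipelineResult:
    """End-to-end haplotype-based risk prediction (five steps, seeded).

    Returns per-test-individual disease probabilities plus the selected
    windows and their statistics.  With no window below ``alpha`` the
    learner is skipped and every test individual gets risk 0.5.
    """
    train_phenotype.require_both_classes()
    groups_half, stat_half = _stratified_half_split(train_phenotype, seed)
    hap_a = train_haplotypes.subset_individuals(groups_half)
    phe_a = train_phenotype.subset(groups_half)
    hap_b = train_haplotypes.subset_individuals(stat_half)
    phe_b = train_phenotype.subset(stat_half)

    windows = enumerate_windows(train_haplotypes.n_variants, length)
    groups_all: list[HaplotypeGroups] = []
    stats_rows = []
    for w in windows:
        groups = build_groups(*window_haplotype_counts(hap_a, phe_a, w))
        groups_all.append(groups)
        # statistic on the disjoint half; unseen haplotypes assigned by
        # similarity so every second-half haplotype counts once
        sub = hap_b.values[:, w.slice()]
        member = np.array([assign_group(row, groups) for row in sub])
        status = np.repeat(phe_b.status, 2)
        counts = GroupCounts(
            int(((member == 1) & (status == CASE)).sum()),
            int(((member == 1) & (status != CASE)).sum()),
            int(((member == 0) & (status == CASE)).sum()),
            int(((member == 0) & (status != CASE)).sum()),
        )
        try:
            stat, p = m_assoc_test_2g(counts, df=df)
        except ValueError:
            stat, p = 0.0, 1.0
        stats_rows.append(
            {"start": w.start, "length": w.length, "statistic": stat, "p": p}
        )
    window_stats = pd.DataFrame(stats_rows)
    selected = [i for i, row in window_stats.iterrows() if row["p"] < alpha]

    if isinstance(learner, str):
        learner = delegated_learner(learner, seed=seed)

    if not selected:
        risk = np.full(test_haplotypes.n_individuals, 0.5)
        return HaplotypePipelineResult(
            risk, windows, [], window_stats, groups_all, learner
        )

    sel_windows = [windows[i] for i in selected]
    sel_groups = [groups_all[i] for i in selected]
    X_train = _encode_all(hap_b, sel_windows, sel_groups)
    y_train = np.repeat(phe_b.status, 2)
    train_haplotype_predictor(X_train, y_train, learner)

    X_test = _encode_all(test_haplotypes, sel_windows, sel_groups)
    p_hap = np.clip(learner.predict_risk(X_test), _P_CLAMP, 1 - _P_CLAMP)
    risk = combine_risks(p_hap[0::2], p_hap[1::2], genetic_model)
    return HaplotypePipelineResult(
        np.asarray(risk), windows, selected, window_stats, sel_groups, learner
    )
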