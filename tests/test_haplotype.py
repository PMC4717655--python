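import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from polyrisk.data import PhasedHaplotypes, Phenotype
from polyrisk.evaluate import auc
from polyrisk.haplotype import (
    GroupCounts,
    HaplotypeGroups,
    TransmissionCounts,
    Window,
    assign_group,
    build_groups,
    combine_risks,
    encode_features,
    enumerate_windows,
    length_measure,
    m_assoc_test_2g,
    m_tdt_2g,
    run_haplotype_pipeline,
    train_haplotype_predictor,
    window_haplotype_counts,
)
from polyrisk.learners import delegated_learner
from polyrisk.simulate import BlockModel, CausalUnit, RiskModel, simulate_cohort, simulate_pool

HAPS_3 = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
          (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)]

# the published worked example: first-half haplotype counts by class
WORKED_CASE = dict(zip(HAPS_3, [13, 8, 11, 9, 14, 17, 16, 12]))
WORKED_CTRL = dict(zip(HAPS_3, [12, 11, 19, 7, 16, 13, 2, 20]))


class TestWindows:
    def test_count_is_n_minus_l_plus_one(self):
        assert len(enumerate_windows(5, 3)) == 3
        assert [w.start for w in enumerate_windows(5, 3)] == [0, 1, 2]

    def test_length_one_gives_one_window_per_variant(self):
        assert len(enumerate_windows(7, 1)) == 7

    def test_overlong_window_rejected(self):
        with pytest.raises(ValueError):
            enumerate_windows(4, 5)


class TestGroups:
    def test_worked_example_partition(self):
        groups = build_groups(WORKED_CASE, WORKED_CTRL)
        assert groups.g1 == {(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0)}
        assert groups.g2 == {(0, 0, 1), (0, 1, 0), (1, 0, 0), (1, 1, 1)}

    def test_all_tied_counts_give_empty_g1(self):
        counts = {h: 5 for h in HAPS_3}
        groups = build_groups(counts, dict(counts))
        assert groups.g1 == frozenset() and groups.g2 == frozenset(HAPS_3)

    def test_single_case_enriched_haplotype(self):
        groups = build_groups({(0, 1): 3}, {(0, 1): 1})
        assert groups.g1 == {(0, 1)} and groups.g2 == frozenset()

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeGroups(frozenset({(0,)}), frozenset({(0,)}))


class TestStatistics:
    def test_mtdt_balanced_transmissions(self):
        assert m_tdt_2g(TransmissionCounts(20, 20, 40)) == 0.0

    def test_mtdt_known_value(self):
        assert m_tdt_2g(TransmissionCounts(30, 10, 40)) == pytest.approx(10.0)

    def test_mtdt_symmetric_under_group_swap(self):
        a = m_tdt_2g(TransmissionCounts(30, 10, 40))
        b = m_tdt_2g(TransmissionCounts(10, 30, 40))
        assert a == b

    def test_mtdt_empty_rejected(self):
        with pytest.raises(ValueError):
            m_tdt_2g(TransmissionCounts(0, 0, 0))

    def test_worked_example_statistic_and_p(self):
        stat, p = m_assoc_test_2g(GroupCounts(53, 38, 47, 62))
        assert stat == pytest.approx(225 / 91 + 225 / 109, abs=1e-12)
        assert stat == pytest.approx(4.5368, abs=1e-4)
        assert p == pytest.approx(0.033175, abs=1e-6)

    def test_perfect_balance_gives_zero(self):
        stat, p = m_assoc_test_2g(GroupCounts(50, 50, 50, 50))
        assert stat == 0.0 and p == 1.0

    def test_thousand_random_tables_match_formula_oracle(self, rng):
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 60, size=4)
            if a + b + c + d == 0:
                continue
            stat, p = m_assoc_test_2g(GroupCounts(a, b, c, d), df=1)
            expect = 0.0
            if a + b:
                expect += (a - b) ** 2 / (a + b)
            if c + d:
                expect += (c - d) ** 2 / (c + d)
            assert stat == pytest.approx(expect, abs=1e-10)
            assert p == pytest.approx(chi2.sf(expect, 1), abs=1e-10)

    def test_two_df_option(self):
        stat, p = m_assoc_test_2g(GroupCounts(53, 38, 47, 62), df=2)
        assert p == pytest.approx(chi2.sf(stat, 2), abs=1e-12)

    def test_empty_group_contributes_zero(self):
        stat, _ = m_assoc_test_2g(GroupCounts(10, 4, 0, 0))
        assert stat == pytest.approx(36 / 14)

    def test_both_groups_empty_rejected(self):
        with pytest.raises(ValueError):
            m_assoc_test_2g(GroupCounts(0, 0, 0, 0))


class TestLengthMeasure:
    def test_identical_haplotypes(self):
        assert length_measure((1, 0, 1, 1, 0), (1, 0, 1, 1, 0)) == 5

    def test_complementary_haplotypes(self):
        assert length_measure((1, 1, 1), (0, 0, 0)) == 0

    def test_interior_mismatch(self):
        assert length_measure((1, 0, 0, 1, 0), (1, 0, 1, 1, 0)) == 2

    def test_symmetry_and_bound(self, rng):
        for _ in range(50):
            a = tuple(rng.integers(0, 2, size=6))
            b = tuple(rng.integers(0, 2, size=6))
            assert length_measure(a, b) == length_measure(b, a)
            assert 0 <= length_measure(a, b) <= 6
            assert length_measure(a, a) == 6

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            length_measure((1, 0), (1, 0, 1))


class TestAssignGroup:
    GROUPS = HaplotypeGroups(
        frozenset({(1, 1, 1, 1)}), frozenset({(0, 0, 0, 0), (1, 1, 0, 0)})
    )

    def test_exact_members_keep_their_group(self):
        assert assign_group((1, 1, 1, 1), self.GROUPS) == 1
        assert assign_group((0, 0, 0, 0), self.GROUPS) == 0

    def test_unseen_closest_to_g2(self):
        # (0,0,0,1): best run vs g1 = 1, vs (0,0,0,0) = 3 -> low risk
        assert assign_group((0, 0, 0, 1), self.GROUPS) == 0

    def test_unseen_closest_to_g1(self):
        # (1,1,1,0): run of 3 vs g1; runs vs g2 members are 1 and 2
        assert assign_group((1, 1, 1, 0), self.GROUPS) == 1

    def test_tie_resolves_low_risk(self):
        groups = HaplotypeGroups(frozenset({(1, 1, 0)}), frozenset({(0, 1, 1)}))
        # (1,1,1): run 2 against both members -> tie -> 0
        assert assign_group((1, 1, 1), groups) == 0


class TestFeatures:
    def test_bits_match_assign_group(self):
        windows = [Window(0, 2), Window(1, 2)]
        groups = [
            HaplotypeGroups(frozenset({(1, 1)}), frozenset({(0, 0)})),
            HaplotypeGroups(frozenset({(1, 0)}), frozenset({(0, 1)})),
        ]
        hap = np.array([1, 1, 0])
        bits = encode_features(hap, windows, groups)
        assert list(bits) == [
            assign_group((1, 1), groups[0]), assign_group((1, 0), groups[1])
        ]

    def test_all_g1_haplotype_is_all_ones(self):
        windows = [Window(0, 2), Window(1, 2)]
        groups = [
            HaplotypeGroups(frozenset({(1, 1)}), frozenset()),
            HaplotypeGroups(frozenset({(1, 1)}), frozenset()),
        ]
        assert list(encode_features(np.array([1, 1, 1]), windows, groups)) == [1, 1]

    def test_empty_window_selection(self):
        assert encode_features(np.array([1, 0]), [], []).size == 0


class TestCombineRisks:
    def test_additive_neutral(self):
        assert combine_risks(0.5, 0.5, "additive") == pytest.approx(0.5)

    def test_additive_adds_log_odds(self):
        from scipy.special import expit, logit

        p = expit(1.0)
        assert combine_risks(p, p, "additive") == pytest.approx(expit(2.0))

    def test_dominant_takes_max(self):
        assert combine_risks(0.3, 0.8, "dominant") == pytest.approx(0.8)

    def test_recessive_takes_min(self):
        assert combine_risks(0.3, 0.8, "recessive") == pytest.approx(0.3)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            combine_risks(0.5, 0.5, "codominant")


class TestPredictorTraining:
    def test_two_instances_per_individual(self):
        haps = PhasedHaplotypes(np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8))
        phen = Phenotype(np.array([1, 0]))
        case_counts, ctrl_counts = window_haplotype_counts(haps, phen, Window(0, 2))
        assert sum(case_counts.values()) == 2 * phen.n_cases
        assert sum(ctrl_counts.values()) == 2 * phen.n_controls

    def test_separable_features_reach_auc_one(self):
        X = np.array([[1]] * 10 + [[0]] * 10, dtype=np.int8)
        y = np.array([1] * 10 + [0] * 10)
        learner = train_haplotype_predictor(X, y, delegated_learner("nbc"))
        assert auc(learner.predict_risk(X), y) == 1.0

    def test_nbc_learner_matches_hand_bayes_on_one_window(self):
        X = np.array([[1]] * 6 + [[0]] * 4 + [[1]] * 2 + [[0]] * 8, dtype=np.int8)
        y = np.array([1] * 10 + [0] * 10)
        learner = train_haplotype_predictor(X, y, delegated_learner("nbc"))
        # add-1 smoothed categorical conditionals over {0,1,2,missing}
        p1_case = (6 + 1) / (10 + 4)
        p1_ctrl = (2 + 1) / (10 + 4)
        expect = 0.5 * p1_case / (0.5 * p1_case + 0.5 * p1_ctrl)
        assert learner.predict_risk(np.array([[1]]))[0] == pytest.approx(expect, abs=1e-10)


def _phased_cohort(with_signal: bool, n_per_class: int, seed: int):
    block = BlockModel(n_blocks=3, block_length=5, founders_per_block=4,
                       recombination_rate_between_blocks=0.5)
    pool = simulate_pool(block, 600, seed=seed)
    units = []
    if with_signal:
        # make one observed 3-SNP haplotype pattern causal
        pattern = tuple(int(v) for v in pool[0, 5:8])
        units = [CausalUnit(effect=np.log(3.0), window=(5, 3), pattern=pattern)]
    model = RiskModel(units, prevalence=0.1 if with_signal else 0.5)
    haps, _, phen, _ = simulate_cohort(pool, model, n_per_class, n_per_class, seed + 1)
    return haps, phen


class TestPipeline:
    def test_null_data_auc_near_half(self):
        from polyrisk.evaluate import holdout_split

        haps, phen = _phased_cohort(False, 150, seed=31)
        train, test = holdout_split(phen, seed=1)
        result = run_haplotype_pipeline(
            haps.subset_individuals(train), phen.subset(train),
            haps.subset_individuals(test), length=3, alpha=0.05,
            learner="nbc", seed=5,
        )
        test_auc = auc(result.test_risk, phen.subset(test).status)
        # null AUC sd at 50/50 split of 100 is ~0.058
        assert abs(test_auc - 0.5) < 0.2

    def test_causal_haplotype_detected_and_predictive(self):
        from polyrisk.evaluate import holdout_split

        haps, phen = _phased_cohort(True, 400, seed=41)
        train, test = holdout_split(phen, seed=2)
        result = run_haplotype_pipeline(
            haps.subset_individuals(train), phen.subset(train),
            haps.subset_individuals(test), length=3, alpha=0.01,
            learner="nbc", seed=6,
        )
        assert len(result.selected) > 0
        test_auc = auc(result.test_risk, phen.subset(test).status)
        assert test_auc > 0.55

    def test_same_seed_identical_scores(self):
        from polyrisk.evaluate import holdout_split

        haps, phen = _phased_cohort(True, 100, seed=51)
        train, test = holdout_split(phen, seed=3)
        kwargs = dict(length=2, alpha=0.1, learner="nbc", seed=9)
        r1 = run_haplotype_pipeline(
            haps.subset_individuals(train), phen.subset(train),
            haps.subset_individuals(test), **kwargs,
        )
        r2 = run_haplotype_pipeline(
            haps.subset_individuals(train), phen.subset(train),
            haps.subset_individuals(test), **kwargs,
        )
        np.testing.assert_array_equal(r1.test_risk, r2.test_risk)

    def test_halves_are_disjoint(self):
        from polyrisk.haplotype import _stratified_half_split

        phen = Phenotype(np.array([1] * 51 + [0] * 49))
        a, b = _stratified_half_split(phen, seed=3)
        assert len(np.intersect1d(a, b)) == 0
        assert len(a) + len(b) == 100

    def test_no_selected_window_gives_flat_risk(self):
        from polyrisk.evaluate import holdout_split

        haps, phen = _phased_cohort(False, 50, seed=61)
        train, test = holdout_split(phen, seed=4)
        result = run_haplotype_pipeline(
            haps.subset_individuals(train), phen.subset(train),
            haps.subset_individuals(test), length=2, alpha=1e-12,
            learner="nbc", seed=2,
        )
        assert (result.test_risk == 0.5).all()
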