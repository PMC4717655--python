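from itertools import combinations

import numpy as np
import pytest

from polyrisk.boosting import (
    CATEGORY_ORDER,
    StumpEnsemble,
    StumpRule,
    fit_weighted_stump,
    merge_rules,
    score_ensemble,
    score_ensemble_matrix,
    train_adaboost_m1,
)
from polyrisk.data import MISSING, GenotypeMatrix, Phenotype, VariantTable
from polyrisk.evaluate import auc
from polyrisk.learners import available_learners, delegated_learner


def stump_oracle(values, status, weights):
    """Brute force over every (variant, proper subset, vote) candidate."""
    n, m = values.shape
    healthy = status == 0
    best_key, best = None, None
    for j in range(m):
        observed = [v for v in CATEGORY_ORDER if v in set(values[:, j])]
        if len(observed) < 2:
            continue
        subsets = [
            combo
            for size in range(1, len(observed))
            for combo in combinations(observed, size)
        ]
        for s_rank, combo in enumerate(subsets):
            fires = np.isin(values[:, j], combo)
            for vote_healthy in (True, False):
                pred_healthy = fires == vote_healthy
                err = float(weights[pred_healthy != healthy].sum())
                key = (err, j, len(combo), s_rank, not vote_healthy)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (j, frozenset(combo), vote_healthy, err)
    return best


def adaboost_oracle(values, status, n_rounds):
    """Straight transcription of AdaBoost.M1 bookkeeping, round by round."""
    n = len(status)
    D = np.full(n, 1.0 / n)
    healthy = status == 0
    log = []
    for _ in range(n_rounds):
        j, subset, vote_healthy, err = stump_oracle(values, status, D)
        if err >= 0.5:
            break
        alpha = np.log((1 - err) / max(err, 1e-10))
        log.append((j, subset, vote_healthy, err, alpha, D.copy()))
        if err <= 0:
            break
        fires = np.isin(values[:, j], list(subset))
        correct = (fires == vote_healthy) == healthy
        D = D * np.where(correct, err / (1 - err), 1.0)
        D = D / D.sum()
    return log


class TestWeightedStump:
    def test_perfect_separator_found(self):
        values = np.array([[0], [0], [1], [2]], dtype=np.int8)
        phen = Phenotype(np.array([0, 0, 1, 1]))
        rule, err = fit_weighted_stump(
            GenotypeMatrix(values), phen, np.full(4, 0.25)
        )
        assert err == 0.0
        assert rule.genotypes == frozenset({0}) and rule.vote_healthy

    def test_matches_exhaustive_oracle_on_random_toys(self, rng):
        for _ in range(30):
            values = rng.integers(0, 3, size=(8, 3)).astype(np.int8)
            values[rng.random((8, 3)) < 0.15] = MISSING
            status = rng.integers(0, 2, size=8)
            if status.min() == status.max():
                continue
            # dyadic weights make every error sum exact, so tie-breaking is
            # bit-for-bit comparable between the two routes
            weights = rng.integers(1, 16, size=8) / 64.0
            rule, err = fit_weighted_stump(
                GenotypeMatrix(values), Phenotype(status), weights
            )
            oj, oset, ovote, oerr = stump_oracle(values, status, weights)
            assert err == pytest.approx(oerr / weights.sum(), abs=1e-12)
            assert (rule.variant, rule.genotypes, rule.vote_healthy) == (oj, oset, ovote)

    def test_null_features_give_half_error_and_deterministic_rule(self):
        values = np.array([[0], [1], [0], [1]], dtype=np.int8)
        phen = Phenotype(np.array([0, 0, 1, 1]))
        rule, err = fit_weighted_stump(GenotypeMatrix(values), phen, np.full(4, 0.25))
        assert err == pytest.approx(0.5)
        # tie rule: lowest variant, smallest subset ({0}), healthy vote first
        assert rule.variant == 0 and rule.genotypes == frozenset({0})
        assert rule.vote_healthy

    def test_single_class_input_degenerates(self):
        values = np.array([[0], [1]], dtype=np.int8)
        rule, err = fit_weighted_stump(
            GenotypeMatrix(values), Phenotype(np.array([0, 0])), np.full(2, 0.5)
        )
        assert err == 0.0 and rule.vote_healthy


class TestAdaBoost:
    def test_one_iteration_is_best_stump_weight_one(self, rng):
        values = rng.integers(0, 3, size=(12, 4)).astype(np.int8)
        status = np.array([0, 1] * 6)
        ensemble = train_adaboost_m1(GenotypeMatrix(values), Phenotype(status), 1)
        assert len(ensemble.rules) == 1
        assert ensemble.rules[0].weight == pytest.approx(1.0)

    def test_three_rounds_match_manual_iteration(self):
        values = np.array(
            [[0, 2, 1], [0, 1, 0], [1, 2, 2], [1, 0, 1],
             [2, 0, 0], [2, 1, 2], [0, 0, 2], [1, 1, 1]],
            dtype=np.int8,
        )
        status = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        oracle_log = adaboost_oracle(values, status, 3)
        assert len(oracle_log) == 3, "fixture must sustain 3 informative rounds"
        ensemble = train_adaboost_m1(GenotypeMatrix(values), Phenotype(status), 3)
        alphas = ensemble.raw_alphas
        assert len(alphas) == 3
        total = sum(x[4] for x in oracle_log)
        for rule, (j, subset, vote, err, alpha, D) in zip(ensemble.rules, oracle_log):
            assert (rule.variant, rule.genotypes, rule.vote_healthy) == (j, subset, vote)
            assert rule.weight == pytest.approx(alpha / total, abs=1e-12)
        for a, (_, _, _, err, alpha, _) in zip(alphas, oracle_log):
            assert a == pytest.approx(alpha, abs=1e-12)
            assert err < 0.5

    def test_instance_weights_renormalized_every_round(self):
        # replicated by the oracle: weights must sum to 1 after each update
        values = np.array(
            [[0, 2, 1], [0, 1, 0], [1, 2, 2], [1, 0, 1],
             [2, 0, 0], [2, 1, 2], [0, 0, 2], [1, 1, 1]],
            dtype=np.int8,
        )
        status = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        for *_ignore, D in adaboost_oracle(values, status, 3):
            assert D.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ensemble_weights_sum_to_one(self, rng):
        values = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
        status = rng.integers(0, 2, size=30)
        status[:2] = [0, 1]
        ensemble = train_adaboost_m1(GenotypeMatrix(values), Phenotype(status), 20)
        assert sum(r.weight for r in ensemble.rules) == pytest.approx(1.0, abs=1e-9)

    def test_ensemble_beats_single_stump_on_training_auc(self, rng):
        values = rng.integers(0, 3, size=(60, 6)).astype(np.int8)
        latent = values[:, 0] + values[:, 3]
        status = (latent + rng.integers(0, 2, size=60) > 2).astype(int)
        if status.min() == status.max():
            pytest.skip("degenerate draw")
        g, p = GenotypeMatrix(values), Phenotype(status)
        single = train_adaboost_m1(g, p, 1)
        many = train_adaboost_m1(g, p, 30)
        auc_single = auc(1 - score_ensemble_matrix(single, g), status)
        auc_many = auc(1 - score_ensemble_matrix(many, g), status)
        assert auc_many >= auc_single - 1e-12

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            train_adaboost_m1(
                GenotypeMatrix(np.zeros((4, 1), dtype=np.int8)),
                Phenotype(np.array([0, 0, 1, 1])), 0,
            )


class TestScoring:
    def test_single_rule_inside_set(self):
        ens = StumpEnsemble([StumpRule(0, frozenset({0}), True, 1.0)], True)
        assert score_ensemble(ens, np.array([0])) == 1.0
        assert score_ensemble(ens, np.array([2])) == 0.0

    def test_probabilities_complementary(self, rng):
        values = rng.integers(0, 3, size=(20, 4)).astype(np.int8)
        status = np.array([0, 1] * 10)
        ens = train_adaboost_m1(GenotypeMatrix(values), Phenotype(status), 10)
        p1 = score_ensemble_matrix(ens, GenotypeMatrix(values))
        assert ((0 <= p1) & (p1 <= 1)).all()
        flipped = StumpEnsemble(
            [StumpRule(r.variant, r.genotypes, not r.vote_healthy, r.weight)
             for r in ens.rules], True,
        )
        p0 = score_ensemble_matrix(flipped, GenotypeMatrix(values))
        np.testing.assert_allclose(p1 + p0, 1.0, atol=1e-12)

    def test_unnormalized_ensemble_normalized_on_the_fly(self):
        ens = StumpEnsemble([StumpRule(0, frozenset({0}), True, 2.0)], False)
        assert score_ensemble(ens, np.array([0])) == pytest.approx(1.0)


class TestMergeRules:
    def test_identical_rules_merge_and_conserve_weight(self):
        ens = StumpEnsemble(
            [StumpRule(0, frozenset({0}), True, 0.1),
             StumpRule(0, frozenset({0}), True, 0.2),
             StumpRule(1, frozenset({1, 2}), False, 0.7)],
            True,
        )
        table = merge_rules(ens)
        assert len(table) == 2
        assert table["weight"].sum() == pytest.approx(1.0)
        merged = table[table["variant"] == 0].iloc[0]
        assert merged["weight"] == pytest.approx(0.3)
        assert merged["genotypes"] == "{0}"

    def test_annotation_and_sorting(self, small_variants):
        ens = StumpEnsemble(
            [StumpRule(3, frozenset({0, MISSING}), True, 0.5),
             StumpRule(0, frozenset({2}), True, 0.5)],
            True,
        )
        table = merge_rules(ens, small_variants)
        assert list(table["snp"]) == ["rs1", "rs4"]
        assert table.loc[0, "genotypes"] == "{2}"
        assert table.loc[1, "genotypes"] == "{0, missing}"


class TestDelegatedLearners:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            delegated_learner("perceptron")

    @pytest.mark.parametrize("name", ["tree", "forest20", "lasso", "ridge",
                                      "nbc", "anbc", "grs", "wgrs", "adaboost"])
    def test_separable_toy_reaches_training_auc_one(self, name):
        values = np.array([[0]] * 10 + [[2]] * 10, dtype=np.int8)
        y = np.array([0] * 10 + [1] * 10)
        learner = delegated_learner(name, seed=0)
        if name == "adaboost":
            learner.n_iterations = 5
        learner.fit(values, y)
        assert auc(learner.predict_risk(values), y) == 1.0

    def test_forest_deterministic_given_seed(self, rng):
        X = rng.integers(0, 3, size=(40, 5)).astype(float)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        r1 = delegated_learner("forest20", seed=3).fit(X, y).predict_risk(X)
        r2 = delegated_learner("forest20", seed=3).fit(X, y).predict_risk(X)
        np.testing.assert_array_equal(r1, r2)

    def test_forest_depth_capped_at_six(self, rng):
        X = rng.random((300, 8))
        y = (rng.random(300) < 0.5).astype(int)
        learner = delegated_learner("forest20", seed=1).fit(X, y)
        depths = [t.get_depth() for t in learner.estimator.estimators_]
        assert len(depths) == 20 and max(depths) <= 6

    def test_stepwise_aic_recovers_informative_feature(self, rng):
        X = rng.integers(0, 3, size=(150, 5)).astype(float)
        logits = 1.5 * (X[:, 2] - 1)
        y = (rng.random(150) < 1 / (1 + np.exp(-logits))).astype(int)
        learner = delegated_learner("stepwise_aic").fit(X, y)
        assert 2 in learner.selected
        risk = learner.predict_risk(X)
        assert auc(risk, y) > 0.6
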