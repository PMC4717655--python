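"""Train a small stump-boosting model and print it as an interpretable
rule table; verify the published reference model's scoring rule.

A 10-round AdaBoost.M1 model on the holdout training half is merged
into one row per (SNP, genotype set, vote) with normalized weights —
the representation in which a genome profile is read off by summing the
weights of the rules a genotype vector fires.  The table goes to
results/06_stump_model.tsv.  As a fixed-point check, the published
7-SNP reference model is scored on its worked-example genotype vector
and must return the published healthy-class probability exactly.
"""

import numpy as np

from common import RESULTS, SEED, study_cohort
from polyrisk.association import pvalues_for_all, select_by_threshold
from polyrisk.boosting import merge_rules, score_ensemble
from polyrisk.cli import stage_seed
from polyrisk.evaluate import auc, holdout_split
from polyrisk.learners import delegated_learner
from polyrisk.reference_models import (
    WORKED_EXAMPLE_GENOTYPES,
    WORKED_EXAMPLE_P_HEALTHY,
    t1d_stump_model,
)

haps, genos, phen, truth = study_cohort()
variants = truth["variants"]
train_idx, test_idx = holdout_split(phen, seed=stage_seed(SEED, "holdout"))

g_train, y_train = genos.subset_individuals(train_idx), phen.subset(train_idx)
p = pvalues_for_all(g_train, y_train)
idx = select_by_threshold(p, 0.05)
learner = delegated_learner("adaboost", n_iterations=10)
learner.fit(g_train.values[:, idx], y_train.status)

table = merge_rules(learner.ensemble, variants.subset(idx))
RESULTS.mkdir(exist_ok=True)
table.to_csv(RESULTS / "06_stump_model.tsv", sep="\t", index=False,
             float_format="%.4f")

risk = learner.predict_risk(genos.subset_individuals(test_idx).values[:, idx])
test_auc = auc(risk, phen.subset(test_idx).status)
print(f"{len(idx)} SNPs selected; 10-round stump model has {len(table)} merged "
      f"rules; holdout test AUC {test_auc:.4f}")
print(table.to_string(index=False, float_format="%.4f".__mod__))

ensemble, _ = t1d_stump_model()
p1 = score_ensemble(ensemble, WORKED_EXAMPLE_GENOTYPES)
assert abs(p1 - WORKED_EXAMPLE_P_HEALTHY) < 1e-10
print(f"reference stump model worked example: p(healthy) = {p1:.10f} "
      f"(published {WORKED_EXAMPLE_P_HEALTHY})")
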