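# Methods

## Data model and coding conventions

Genotypes are copies of allele 1 (0/1/2) with −1 for missing; allele 1
is the first allele encountered in PED file order and is recorded per
variant so log-odds-ratio signs are reproducible.  Phased haplotypes
are binary rows, two consecutive rows per individual, and satisfy
h₁ + h₂ = genotype wherever the genotype is observed; the HAPS/SAMPLE
format carries no missing alleles, so missingness lives only in the
genotype matrix.  Phenotypes are stored as 1 = case.  Stump-model
report tables follow the opposite convention of the published tables
they mirror ("class 1" = healthy); that mapping is metadata, never a
recoding of stored data.

## Synthetic cohorts

The generator emulates what the pipelines need from chip-genotyped
case/control data and nothing more.

*LD structure.*  Haplotypes are mosaics of founder haplotypes over
blocks of `block_length` SNPs.  A pool haplotype draws a founder index
for block 1 from the founder frequency vector and carries it across
each block boundary, redrawing with probability
`recombination_rate_between_blocks` (default 0.5); within-block
recombination is 0, so blocks are perfect LD units and between-block
correlation decays geometrically.  Founder alleles are Bernoulli draws
at per-site frequencies Uniform(0.05, 0.5) (optionally a fraction of
sites below 1 % to exercise the MAF filter).  Defaults (10 blocks × 5
SNPs × 4 founders) give realistic-looking blockwise r² at desk scale.

*Risk model.*  Disease status is Bernoulli at
expit(c + Σ_u β_u a_u(dose_u)), where each causal unit u is either a
variant (dose = allele count) or a (window, haplotype-pattern) pair
(dose = copies of the pattern in the diplotype), β_u is its log odds
ratio and a_u applies the genetic action: additive = dose, dominant =
1{dose ≥ 1}, recessive = 1{dose = 2}.  The two haplotypes of an
individual are independent draws from the pool (linkage equilibrium
between homologs, the same assumption the haplotype predictor makes).
The intercept c is found by Brent root-finding so that the mean disease
probability over a 20 000-diplotype Monte-Carlo sample of the pool
equals the target prevalence K; exact case/control counts are then
filled by rejection sampling.  An unattainable K (e.g. a degenerate
pool whose liability floor exceeds it) raises rather than silently
shifting the effect sizes.

*What it does not emulate:* population stratification, relatedness,
genotyping batch effects, realistic recombination maps, phasing error
(truth is phased by construction).  Consequently, passing tests show
the *methods* behave correctly under their own assumptions — not that
those assumptions hold in any real cohort; in particular the absence of
stratification means null calibration here is a necessary, not
sufficient, condition for real-data validity.

## SNP cleaning

Hardy–Weinberg is a 1-df χ² goodness-of-fit against expected genotype
counts from the estimated allele frequency, computed separately in
cases and in controls; a variant is excluded when p < α (default 0.05)
in *either* stratum.  The published rule ("p < 0.05 in cases and
controls") is ambiguous between either- and both-stratum exclusion; the
stricter either-stratum reading is the default and `hwe_strata="both"`
is available.  Differential missingness is a Pearson 1-df χ² (no
continuity correction) on the 2×2 missing/observed × case/control
table, degenerate margins giving p = 1 with a warning.  MAF is the
folded allele-1 frequency over non-missing genotypes; the default floor
is 1 %.  Individuals are never removed; the filter is idempotent.

## Association and selection

The Cochran–Armitage trend test uses fixed scores (0, 1, 2):
T = Σ s_i (S c_i − R k_i), Var T = (RS/N)(N Σ s_i² n_i − (Σ s_i n_i)²),
statistic T²/Var ~ χ²(1).  Monomorphic tables return (0, 1).  Missing
genotypes are dropped per variant (complete cases per SNP).  Selection
is p < α over the standard threshold grid
{0.8, 0.5, 0.1, 0.05, 0.01, 10⁻³, 10⁻⁴, 10⁻⁵}, or top-K by rank
(default K = 100) with ties broken by variant order.  All selection is
re-run inside each training fold.

## Score-based predictors

Allelic ln OR weights come from the 2×2 allele-by-status table with 0.5
added to every cell when any cell is zero, so weights are always
finite.  GRS/wGRS treat missing genotypes as 0 risk alleles (equivalent
to imputing the non-risk homozygote — the simplest reproducible
choice).  wGRS sums are correctly rounded (math.fsum): individuals
whose scores tie in real arithmetic get bit-identical doubles, which
keeps the wGRS ranking exactly equal to the allelic-naïve-Bayes log
odds α₀ + Σ w_i x_i (slope fixed at 1,
α₀ = ln p(D)/(1−p(D)) + 2 Σ ln[p(h_i=0|D)/p(h_i=0|D̄)]) — the AUC
equivalence of the two models is asserted exactly in the tests.  The
closed form is implemented with index i throughout (one published
rendering of it carries an obvious h₁-for-h_i index typo).  The
one-covariate logistic link is Newton–Raphson (tolerance 1e-8, ≤ 100
iterations); under separation the slope is clamped at |α₁| = 25 and the
intercept refit at the clamp.  Genotype naïve Bayes uses four
categories per SNP (0/1/2/missing) with add-1 smoothing and log-space
products.

## Stump boosting

The weak learner searches *all* non-empty proper subsets of the
genotype values observed at each variant (≤ 4 categories, missing
included, hence ≤ 14 subsets), both vote orientations, minimizing
weighted misclassification computed from per-value class-weight sums
(O(n) per variant).  Ties break toward the lower variant index, the
smaller subset (then enumeration order), and the healthy vote, making
training fully deterministic.  AdaBoost.M1 follows the standard
bookkeeping: α_t = ln((1−ε_t)/ε_t), correct instances downweighted by
ε_t/(1−ε_t), renormalization each round, early stop at ε_t ≥ 0.5 (the
weak-learner condition fails routinely on small data at large iteration
counts — this is logged, not an error) or ε_t = 0 (terminal rule kept,
α capped via ε ← 1e-10).  The reported ensemble normalizes rule weights
to sum 1 and merges identical (variant, subset, vote) rules; raw α_t
are retained for the unnormalized representation some published tables
use.  Scoring adds the weights of the rules whose vote for the given
vector is class 1 (a rule votes its class inside its genotype subset
and the opposite class outside); it never re-divides by the weight sum,
because the published worked example sums printed (rounded) weights
as-is — a flagged-normalized ensemble therefore tolerates print-level
deviation from 1, while ensembles built by training sum to 1 within
1e-9.

## Haplotype pipeline

Training individuals are split 50/50 (stratified, seeded).  Groups: a
window haplotype joins g1 iff strictly more frequent in case than in
control haplotypes of the first half; ties go to g2 (g1 is defined
strictly as case-enriched).  The statistic half contributes counts by
group membership — unseen haplotypes are assigned by similarity, so
every haplotype counts exactly once — and the two-group statistic gets
a χ² tail with df = 1 by default: the published worked example's
p = 0.033175 equals the 1-df tail of 4.5368 (the 2-df tail would be
0.103), so df = 1 reproduces that arithmetic; df = 2 is exposed since
the asymptotic null of the statistic is not derived anywhere and one
published sentence asserts 2 df.  A degenerate window (both groups
empty on the statistic half) scores (0, 1).  Similarity is the length
measure (longest run of consecutive matching alleles); assignment ties
resolve to low risk.  The haplotype-risk learner sees one binary
membership bit per selected window and two labelled instances per
individual (case ⇒ both haplotypes high-risk).  Per-individual
combination: additive = expit(logit p₁ + logit p₂) (multiplicative on
odds), dominant = max, recessive = min — max/min is our
operationalization of dominant/recessive action on the absolute
haplotype risks; the original formulation does not pin this down.
Probabilities are clamped to [1e-12, 1−1e-12] before the logit.
Window lengths 1–5 are supported (published usage varies between 1–5
and 2–5; the full range is the default).

## Evaluation

AUC is the Mann–Whitney rank form with ties counting one half (exactly
the all-pairs probability that a case outranks a control).  Confusion
metrics threshold the risk at 0.5; empty denominators give NaN.  Folds
are stratified (plain random splitting can empty a class at desk
scale); the headline summary is the fold median, with mean/min/max
stored.  Holdout is a stratified 50/50 split with a `swap` option for
model-reproducibility experiments; with an odd class the extra
individual lands in the test half.  Fold-wise AUC vectors are compared
with an exact two-sided Wilcoxon signed-rank or a paired t test
(scipy).  The fit/score contract passes training-fold data only to
fitting code, so test-fold phenotypes cannot leak into selection or
weights; a regression test checks that full-data selection on null data
inflates CV AUC relative to in-fold selection.

## Determinism

Every stochastic step takes an explicit seed; the CLI fans a single
mandatory global seed out to stage-specific sub-seeds by SHA-256 of
`"{seed}:{stage}"` (kept below 2³¹).  Identical config + seed
reproduces reports byte for byte.

## Problem sizes and calibration checks

The test suite and analysis scripts run at desk scale, chosen so the
statistical assertions have known behavior: parameter recovery uses 20
cohorts of 4 000 individuals (per-allele ln OR sampling s.e. ≈ 0.05 at
MAF 0.3, so a ±0.1 recovery band is a ≈2σ per-seed check and a sharp
bias check on the 20-seed mean); null calibration uses 20 replicates of
a 200-individual, 40-SNP cross-validated pipeline; the analysis cohort
is 600 individuals × 50 SNPs.

One calibration bound is knowingly above what its generative scenario
can deliver and is kept anyway: a single additive causal 3-SNP
haplotype at per-copy OR 3 has a likelihood-ratio AUC ceiling of
max_q AUC ≈ 0.696 (dose x ~ Binom(2, q), case distribution ∝ prior·3^x
as prevalence → 0; lower at higher prevalence, lower still under
dominant/recessive action), so the corresponding > 0.7 test documents
the ceiling in its docstring and fails by construction (measured 0.692
at the study seed).  Raising the injected OR would pass it trivially;
we prefer the stated conditions plus the analysis.

## Known limitations

- The stump search is exhaustive over ≤ 4 genotype categories; it does
  not generalize to multi-allelic variants.
- The trio statistic mTDT_2G is a formula only; no pedigree bookkeeping.
- No covariates anywhere (the protocol inherits individual-level QC
  from upstream and models genotype-only risk).
- The haplotype pipeline assumes phased input without missing alleles;
  phasing uncertainty is outside scope.
- Stepwise-AIC is forward-only with a feature cap (default 20) for
  tractability.
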