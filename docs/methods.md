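# Methods

This note documents the statistical procedures the package implements,
the modelling assumptions behind the synthetic cohort generator, the
defaults and why they were chosen, and the limits of what the test
suite can establish about real data.

## Cohort semantics and eligibility

A cohort is one row per participant: 23 binary symptom endorsements on
three self-rating scales (11 depressive-like, 6 hypomanic-like, 6
psychotic-like items), a binary family-history flag (any mood or
psychotic disorder in 1st/2nd-degree relatives), three binary CIDI
syndrome flags whose OR defines trans-diagnostic caseness, and ages for
the symptom self-rating, the diagnostic interview and (for cases)
syndrome onset.  The eligibility filter enforces antecedence: a record
is kept only when the interview age and any caseness onset *strictly*
follow the self-rating age.  Strictness is a deliberate choice — equal
ages cannot establish that symptoms preceded the outcome — and records
with missing required ages are excluded rather than imputed, matching a
complete-case policy.  Exclusions are logged with machine-readable
reasons, filtering is idempotent, and included plus excluded counts
always equal the input count.

The exact 23-item wording is instrument-specific and not fully public;
the registry pins the twelve codes that rules and reports reference
(sadness DLE2, feeling overwhelmed DLE4, hypersomnia DLE8, sleep
quality DLE10, concentration DLE11, elation HMLE1, need for sleep
HMLE3, physical activity HMLE5, and the psychotic items PLE2, PLE3,
PLE5, PLE6) and treats the remaining labels as placeholders.  The
registry, like the subthreshold rule set, is configuration rather than
a constant.

## Risk exposures

* **Symptom load** is the count of endorsed items (0–23).
* **High load** is `load > median(load)`, strictly greater, with the
  lower-median convention for even n (the sorted element at ⌈n/2⌉).
  The threshold is always recomputed in-sample.
* **Subthreshold syndromes** default to: depressive = sadness (DLE2)
  required plus ≥4 depressive-scale items; hypomanic = elation (HMLE1)
  required plus ≥3 hypomanic items; psychotic = ≥2 psychotic items.
  These mirror common subthreshold conventions; since published rule
  sets vary, the entire rule set is a YAML-configurable object and no
  rule is hard-coded.
* **The variable of influence** packs (age above/below the in-sample
  median rating age) × (sex) × (MZ versus any other sibling status)
  into categories 1–8 (bit encoding: age, sex, zygosity).  Supplying it
  to the tree as an ordinary free-nominal candidate predictor makes the
  model conditionally adjusted for demographics and familial clustering
  wherever those covariates are informative, without overriding the
  depth budget.  An alternative reading — case weighting by influence
  category — exists in some tree software; the predictor reading is the
  default here because it keeps the fitting algorithm unchanged and the
  adjustment inspectable in the fitted tree.

## Predictive values, intervals, AUC

PPV and NPV are computed in Bayes form from sensitivity, specificity
and prevalence.  On any complete 2×2 table the Bayes form is
algebraically identical to the count ratios tp/(tp+fp) and tn/(tn+fn);
the identity is property-tested, and empty margins raise an explicit
undefined-metric error instead of returning silent zeros.

Proportion intervals are standard-logit Wald intervals,
logit(p̂) ± z·√(1/s + 1/f), back-transformed.  Degenerate proportions
(s = 0 or f = 0) get +0.5 added to both cells for the interval only —
point estimates are never adjusted — and the boundary side is pinned at
0 or 100%.  The logit interval was chosen for its boundary behaviour
and common use with predictive values; empirical coverage of the 95%
interval at n = 300, p = 0.4 is verified to lie in [93%, 97%].

AUC is the Mann–Whitney concordance probability computed from midranks,
so ties count ½ — important here because binary exposures make ties
dominant.  For a binary exposure AUC = (Se+Sp)/2 exactly; this and
equality with the trapezoidal ROC area are asserted in tests.
Unadjusted AUC intervals use the Hanley–McNeil variance.
Covariate-adjusted AUCs fit a binomial GLM (logit link, IRLS) of the
outcome on the exposures plus influence-category indicators and apply
Mann–Whitney concordance to the fitted probabilities; intervals come
from a percentile bootstrap that resamples whole families (default 2000
replicates), because observations within a twin/sibling family are not
independent.  With all families of size one this resampler reduces
exactly to the ordinary bootstrap.

## CHAID

For each candidate predictor within a node, categories are merged
bottom-up: the pair of groups (adjacent pair, for ordinal predictors)
with the largest pairwise χ² p-value is merged while that p-value
exceeds α_merge = 0.05; if the final two groups are still
indistinguishable the predictor collapses and is unusable in that node.
The resulting r-group table is scored by Pearson χ² (no continuity
correction) and the p-value multiplied by the Kass Bonferroni
multiplier — the number of ways c observed categories can be reduced to
r groups: C(c−1, r−1) for ordinal predictors, the Stirling number of
the second kind for free-nominal ones.  Both formulas are verified
against exhaustive partition enumeration for c ≤ 6.

The merge step is merge-only: merged compounds are never re-split.
This is exact for binary predictors — the dominant case in a symptom
battery — and a documented simplification of the full Kass algorithm
for multi-category predictors.

Split selection ranks predictors by adjusted p-value, with ties broken
by larger χ² and then registry order (the underlying algorithm is
deterministic; tie behaviour must be too).  In addition to the
merge-multiplier, the selected p-value is multiplied by the number of
candidate predictors.  This across-predictor Bonferroni factor is what
makes the stated family-wise guarantee true: with m independent null
predictors the probability that any of them clears α on its own is
roughly m·α (about 20% for 23 predictors at α = 0.01), whereas with the
factor the no-signal cohort produces a spurious split at no more than
the nominal rate.  The null-control test (23 independent predictors,
n = 1815, 200 simulations) verifies ≤ 5% of runs split.  The factor
also leaves the predictor ranking unchanged, so oracle comparisons of
root choice are unaffected.

Stopping rules are set a priori: α_split = 0.01 (strict comparison),
minimum parent 100, minimum child 50, maximum depth 3 — the
conventional defaults of widely used CHAID implementations, consistent
with published trees of at most three split levels.  A winning split
that would create an undersized child is rejected and the next-best
candidate considered.  Node ids are assigned breadth-first; identical
data and configuration produce byte-identical serialized trees.
Prediction routes records by merged-group membership; an unseen
category falls back to the largest child and the event is flagged.

## Train-test evaluation

The 50/50 split assigns whole families to folds in seeded random order
until the training fold reaches its target fraction.  Family-awareness
prevents leakage through shared liability (an MZ co-twin of a training
case must not appear in the test fold); a per-record mode exists for
unclustered data.  Stratification by outcome is not applied — the
realized fold case rates differ only by sampling noise at these sizes.
All reported numbers (node counts, case percentages, path PPVs/NPVs,
model AUC) come from the held-out fold; the training fold contributes
only the tree structure and the leaf scores.

## The synthetic cohort generator

The generator exists because participant-level cohorts of this kind are
not publicly deposited.  It is a liability-threshold model: families
are twin or sibling pairs (individual zygosity shares 28% MZ / 38% DZ /
34% siblings; an odd cohort size leaves one singleton, mirroring
cohorts where only one co-twin enrols); each family draws a shared
standard-normal factor `a_f`; individual liability is
`L = √ρ·a_f + √(1−ρ)·e` with ρ_MZ > ρ_DZ = ρ_SIB (calibrated defaults
≈ 0.74 / 0.37).  Item j is endorsed iff `λ_j L + √(1−λ_j²)·u_ij > τ_j`,
so the marginal prevalence is exactly Φ(−τ_j) and item thresholds are
set in closed form.  Family history is a family-level threshold on
`a_f` (hence exactly calibrated via z_fh = Φ⁻¹(1−prevalence)), and its
dependence on the same factor that drives liability is what produces a
joint FH∧SubT rate well above the product of the marginals.  Caseness
is `L + fh_effect·FH > z_case` by default, or a Bernoulli draw from a
planted decision tree's leaf probability when a ground-truth tree is
installed.  Onset ages are rounded truncated normals: subthreshold
onset at or before the rating age, caseness onset strictly after it
(the generated cohort passes the eligibility filter untouched).
Caseness splits into CIDI subtype flags by independent thinning
(depressive 0.75, hypo/manic 0.25, psychotic 0.12, forced non-empty),
giving a realistic share of multi-syndrome cases.

### Why the item structure is clumped

The emulated cohort's printed load statistics — median 5, mean 5.21,
and only ~22% of participants *strictly above* the median — jointly
force a probability atom of at least 0.28 at the median: F(median) must
be ≈ 0.78 while F(median−1) < 0.5.  No smooth one-factor item model
produces such an atom.  The calibrated default therefore uses a block
of five near-comonotone "core" items (loadings 0.999, prevalence
≈ 0.55–0.60, including the three most-endorsed codes DLE8, HMLE1,
DLE10) that switch on together across a liability threshold, plus
eighteen items with loadings 0.998 that fire mainly at high liability.
Participants in the wide mid-liability band endorse exactly the five
core items — the atom at load 5 — while the upper ~22% cascade through
the remaining items.  The non-core items form two weight-tied families
whose levels are the calibration knobs: a "neutral" family led by
feeling-overwhelmed (DLE4) that controls the high-load share, and a
"trigger" family led by sadness (DLE2) that completes the subthreshold
rules and controls the SubT rate.  Core composition respects the rule
set (no DLE2, at most two hypomanic items, no psychotic items), so the
core block alone never satisfies a syndrome.

Consequences to keep in mind: the five core items end up slightly above
a 50% prevalence ceiling that real item tables report (~55–60%); the
load standard deviation (≈ 6.3) exceeds the emulated cohort's 4.35; and
symptom profiles are nearly one-dimensional, which makes caseness far
more separable than in real data (tree AUCs in the mid-90s versus
mid-70s).  These are the price of matching the printed median /
high-load / mean triple exactly, and they mean that passing calibration
tests demonstrates control of the *marginal* structure, not realism of
the joint symptom distribution.  Planted-tree benchmarks therefore use
a separate, plainly parameterised configuration (independent items,
moderate prevalences) where the generator's theoretical AUC is
available in closed form from leaf masses and probabilities.

### Calibration

`calibrate_thresholds` tunes, in order: the trigger level (bisection on
the simulated SubT rate), the neutral level (on the high-load share),
a scale on the familial correlations preserving ρ_MZ > ρ_DZ (on the
joint FH∧SubT rate), the caseness threshold (on the caseness rate) and
the onset-age location (on the pooled onset median), with the core
prevalence always derived in closed form so prevalences sum to the
target mean load.  Each bisection evaluates one simulated cohort of
120,000 individuals per step (two sweeps of the interacting knobs), and
a final 400,000-individual simulation verifies every target within its
tolerance (0.0075 absolute on proportions, 0.075 on the mean load, 0.5
years on the onset median, exact population median 5); failure raises
an error naming the unmet target rather than returning a drifted
configuration.  Calibration takes ~15 s on one CPU and is fully
deterministic given its seed.

## Problem sizes used in the shipped checks

The distributed test suite and the results script use the sizes the
methods are designed for: 100 cohorts of n = 1815 for the calibration
marginals (30 in the faster test-suite variant), 100 seeds of n = 5000
for planted-tree recovery, 200 null simulations of n = 1815 × 23
predictors for family-wise control, 10,000 random tables for the
Bayes/count identity, and 2000 replicates for CI coverage.  The whole
suite runs in under a minute beyond the one-off calibration.

## Known limitations

* The generator reproduces marginal rates and the load distribution's
  atoms, not realistic item covariance; see above.
* Caseness in the default configuration is a deterministic threshold on
  latent liability (plus FH), so discrimination ceilings are optimistic.
* The merge-only CHAID variant can differ from full Kass CHAID on
  predictors with ≥3 categories; only the influence variable has more
  than two here.
* Adjusted AUCs condition on fitted probabilities from a correctly
  specified logistic model; model misspecification is not explored.
* No survival/time-to-event modelling of transition: onset ages are
  generated and summarised but never modelled.
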