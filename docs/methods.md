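# Methods

## The frailty instrument

The package quantifies frailty as the reciprocal of a composite fitness
percentage. Two component scores are normalised against a *young wild-type
control group* — every wild-type animal aged at most `control_max_age`
(default 6.0) months, the sub-cohort assumed not yet to show ageing. A
configuration alternative (e.g. a 3–5.5-month window) can be expressed by
changing that one key; the package does not attempt to reconcile the two
conventions silently.

**Physical constitution (Pcs).** Items are scored on the three-level deficit
scale {0, 0.5, 1}. Two items carry explicit observation rules (visual placing
from 2×2 orienting trials; hearing from 3 click trials); all others are
ingested as pre-assigned scores — the package does not invent observation
protocols for coat condition, cataracts, and the like. The penetrance weight
of an item is the fraction of animals affected by it (score < 1), computed by
default over the whole analysed cohort, both genotypes and sexes pooled
(configurable via `penetrance_by_genotype`). An animal's raw score is
Σ fₙ·sₙ / N with N the number of items observed (constant within a run);
Pcs expresses it as percent of the control mean of the same quantity. Items
with penetrance 0 therefore contribute nothing — a 20-item panel collapses
automatically to the subset expressed in the colony.

Note one coupling this weighting creates: because weights are recomputed from
the cohort, worsening one animal's score can raise that item's weight for
*everyone*. Monotonicity ("worsening an input never lowers frailty") holds at
fixed weights and control means, which is how the property is tested; at the
cohort level a newly affected first animal of an item can slightly move other
animals' scores. This is inherent to penetrance weighting, not an
implementation artefact.

**Musculoskeletal function (Mfs).** Trial recording rules: cage-top falls
record the time (≤ 60 s, sub-10 s falls voided and retried); tight-rope falls
record the time, rope traversals record 120 − t, full-duration hangs record
60 s, so recorded values live in [10, 120]; grip strength averages the
Newton-meter gram-force over trials and divides by body weight. Each task is
averaged over its valid trials. A task enters the score only if its wild-type
values correlate with chronological age (two-sided Pearson p below
`screen_alpha`, default 0.05, sexes pooled) — a frailty-relevant task must
track normal ageing per se. Open-field metrics are first-class candidate
tasks, not hard-coded exclusions; under the generator's defaults (no age
signal) they fail the screen at the nominal rate. Mfs is the mean over
included tasks of 100 · animal mean / control mean.

**Frailty.** fitness = (Mfs + Pcs)/2 and frailty = 1000/fitness =
2000/(Mfs+Pcs). The control-level value is exactly 10. The score is reported
unrounded and unbinned. Animals missing either component get a missing
frailty — fitness averages both components, so neither is imputed from the
other. By Jensen's inequality the control-group *mean* of per-animal frailty
sits at or above 10 even though mean fitness is exactly 100; tests assert the
direction, not equality.

## Statistical machinery

All regressions in the association panel share one toolkit
(`frailmicro.stats`):

- **Pearson correlation** with the exact t-transform p
  (t = r·√((n−2)/(1−r²)), n−2 df, two-sided). At very small n this tracks the
  exhaustive permutation null closely but not arbitrarily well: the
  permutation distribution has only n! atoms, so below n = 7 its granularity
  (1/24 of probability mass per ordering at n = 4) exceeds a 0.02 agreement
  band for some datasets. The test suite asserts agreement where the
  mathematics allows it (the n = 4 rank worked example, and universally at
  n = 7) and records the exhaustively-enumerated worst cases for smaller n.
- **Linear fit with 95 % mean-response band**, the textbook
  t·√(MSE·(1/n + (x₀−x̄)²/Sxx)) interval, cross-checked in the tests against
  statsmodels' prediction interval.
- **Slope-equality test**: F = (SS_pooled − SS_separate)/MSE_separate with
  df (1, n_A + n_B − 4), comparing a common-slope/separate-intercepts model
  against separate lines; identical to the group-by-x interaction t-test.
- **Unpaired two-sided t-test**, Student's pooled-variance form by default
  with a Welch flag.
- **ROUT outlier removal** at FDR Q (percent; default 1): an IRLS robust line
  fit with Lorentzian weights w = 1/(1 + (res/RSDR)²), converged when the
  relative change in the weighted residual SS falls below 1e−8 (cap 200
  iterations); the robust scale RSDR is the 68.27th-percentile absolute
  residual (linear-interpolation quantile) times √(n/(n−2)); residuals are
  then tested largest-first against two-sided t tails at n−2 df, flagging
  rank-i points while p < Q·(n−i+1)/(100·n). Exactly tied residuals are
  tested jointly at the worse rank (flag all or none). With n < 5 no removal
  is attempted (warning); with an exactly collinear bulk, any measurably
  off-line point is an outlier and a fully collinear set has none. The flag
  set is invariant to affine rescaling of y. Setting `rout_Q = 0` disables
  the stage entirely.

p-values are never truncated internally; "< 0.0001"-style formatting is left
to report consumers.

## Microbiota quantification

Plate counts: faeces are suspended at 100 µL saline per mg, so CFU/g =
(colonies / counted area fraction) · (total suspension / plated volume) /
faecal mass in grams. Zero colonies is a measured zero, not a detection
failure. qPCR: per replicate, copies = 10^((Ct − intercept)/slope) against a
per-target standard curve (slope < 0); the sample value is the replicate mean
times a per-target copies→bacteria/g factor. Curve parameters and conversion
factors are required inputs per target (the generator emits its own); no
defaults masquerade as laboratory values. A sample with no amplified
replicate is below detection and excluded from associations — never imputed,
matching standard practice for targets near the limit of quantification.
Groups with fewer than `min_evaluable_n` (default 9, borrowed from the
aged-subgroup sufficiency rule) quantifiable samples in either genotype are
dropped from the panel, with the decision logged.

The Bacteroidetes/Firmicutes ratio is computed per animal where both phyla
are quantifiable and treated as one more measure. The aged-subgroup analysis
restricts to animals older than `aged_cutoff` (default 10 months), requires
`min_group_n` (default 9) per genotype, compares measures with the unpaired
t-test, and reports the genotype mean ages with their own t-test so readers
can verify the groups are age-matched.

## The association panel

For each (measure, axis ∈ {age, frailty}, genotype): exclude below-detection
and missing values, remove outliers with ROUT at `rout_Q`, then Pearson
correlation and the linear fit on the cleaned points; per (measure, axis),
compare the two genotype slopes. Every exclusion is logged with the animal
and measure identity, and cell bookkeeping (n_used, n_outliers_removed,
n_missing) accounts for the full genotype cohort. The summary grid renders
↑/↓/− per cell (significant at `sig_alpha`, default 0.05) and '+' where the
genotype slopes differ. Outlier handling is applied per regression — each
cell's cleaning is independent, so a point may be an outlier against age but
not against frailty. Sex-stratified runs (including a female-vs-male slope
comparison within genotype) are available but off by default; the default
report pools sexes within genotype. No multiple-testing correction is
applied across the panel by default — the analysis reports per-cell
correlations as such; a config hook (`sig_alpha`) exists for sensitivity
analyses.

## The synthetic cohort generator

`GeneratorSpec` defaults encode the study conditions: 40 animals per genotype,
50 % female, ages uniform over 3–16 months (a cross-sectional continuous age
design), body weight with sex and age terms.

Each animal carries a latent frailty propensity u ~ N(0, 1) — the
individual quality-of-ageing variation that makes frailty more than a
relabelling of age. It enters additively: each grip task loses
`frailty_scale` task units per unit of u (cage-top 6 s, tight-rope 10 s, grip
0.6 gf/g), and each examination item's affection odds gain `frailty_gain`
(default 1.5) logits per unit of u. Additive, age-independent heterogeneity
was a deliberate design choice over multiplicative (level- or deficit-
proportional) scaling: multiplicative forms make task variance grow with age
and push values into the recording rails, which biases and mis-calibrates
ordinary least-squares slope estimation — the very estimator the recovery
tests exercise. Task means decline linearly in age with a steeper transgenic
slope (`tg_age_slope`); trial noise is Gaussian; recorded values are clipped
to each task's rails (10–60 s cage-top, 10–110 s tight-rope), so very old
transgenics saturate at the floor, as real animals that fail immediately
would. Open-field metrics have no age, genotype or propensity terms and are
expected to be screened out.

Items follow logistic penetrance curves, logit P(affected) = α + β·age +
γ·tg + γ_age·tg·age + gain·u, with an affected animal severe (score 0) with
probability 0.30 and mild (0.5) otherwise. Most expressed items use β = 0.30
per month with a transgenic age interaction γ_age = 0.18; alopecia, cataracts
and adiposity instead carry a negative constant genotype shift (the wild type
shows them more); five items are essentially never expressed, so the 20-item
panel collapses to ~15, exercising the zero-weight dropout.

Microbe log10 abundances follow μ + δ_age·age + δ_age,tg·tg·age + δ_frail·F +
δ_tg·tg + ε, where F is the animal's **latent** frailty: the composite score
computed from its noiseless task means and realised item scores through the
actual scoring formulas (control group and all). The pipeline's estimated
frailty is therefore a noisy proxy of the quantity driving the microbes —
realistic attenuation by construction. Defaults plant the qualitative
study-level patterns: a wild-type-only age increase for Enterobacteriaceae, a
frailty (not age) association for the Schaedler-agar community, age
increases for both dominant phyla, frailty associations for Bifidobacterium
and Bacteroides, a transgenic Bacteroides deficit visible in the aged
subgroup, two targets (Prevotella, C. coccoides) sitting mostly below the
qPCR limit of quantification (replicate Ct > 35 is undetermined), and two
null controls. Plate rows carry Poisson colony counts consistent with the
plating metadata; qPCR rows carry triplicate Cts with 0.15-cycle replicate
noise against per-target standard curves (slope −3.4, intercept 38,
10⁶ copies→bacteria/g).

Randomness flows from a single `rng_seed` through named SeedSequence
substreams (animals, frailty, items, tasks, microbes, outliers), so adding a
table does not shift the others and identical seeds give byte-identical CSVs.
`plant_outliers` displaces a configurable fraction of qPCR rows by a multiple
of the group noise SD, applied to the replicate Cts through the standard
curve so the pipeline sees a coherent gross outlier; planted row indices are
recorded in the ground truth.

**What the generator does and does not emulate.** It reproduces the
statistical *structure* the pipeline assumes — linear declines, logistic
penetrance, lognormal abundances, detection censoring, shared latent
frailty — with effect sizes chosen once so that the planted structure is
recoverable at the design's sample size (screen inclusion of the three grip
tasks, slope recovery within standard coverage, detectable genotype
acceleration, a frailty-over-age detection advantage for frailty-linked
microbes). It does not attempt to match the real study's effect sizes (no
raw data is available), does not model litter, cage, diet or batch effects,
seasonal drift, or compositional coupling between taxa, and its item scores
are conditionally independent given age, genotype and u. Passing tests
therefore demonstrate that the pipeline recovers known structure of this
kind, not that real cohorts satisfy these assumptions.

## Numerical and problem-size choices

Simulation-based tests state their sizes explicitly: calibration checks run
at 400–2000 replicates; recovery checks at 40 cohorts; detection-rate
comparisons at 50 cohorts; the power-hungry sex-stratified planted effect
uses 100 animals per genotype for ~95 % power. Quantile convention for the
RSDR is numpy's linear interpolation. Degenerate inputs (zero variance,
empty control groups, all-undetermined qPCR samples, fully deficient score
profiles) raise located errors or produce logged missing values — never
silent zeros.

## Known limitations

- Penetrance weights are cohort-relative; scores are not comparable across
  cohorts without refitting the control normalisation.
- The screen's inclusion decision is binary at `screen_alpha`; borderline
  tasks can flip between runs of different cohorts (the decision is logged).
- ROUT assumes a mostly-linear bulk with at most ~20 % contamination; the
  generator enforces that regime for planted outliers.
- The frailty–age relation is mildly convex (reciprocal transform), so the
  linear slope comparison between genotypes is a first-order summary; with
  strong saturation at task floors the true difference is underestimated.
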