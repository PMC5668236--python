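# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `microtrait`, at the level of detail a maintainer
or reviewer needs to judge what the package does and does not establish.

## The two-part association model

For each feature (OTU, taxon) and trait, the feature's per-sample relative
abundance `a` is decomposed into presence `b = [a > 0]` and
abundance-given-presence. Three tests are run:

* **Binary**: OLS of the trait on `b` plus covariates. The trait is the
  response and presence the predictor (not logistic regression of presence
  on the trait): this yields β₁ on the trait scale, which the risk score
  needs. Skipped when the prevalence within the analysis set falls outside
  [0.05, 0.95] — a near-constant indicator gives unstable estimates, and
  cross-validation subsets can drift outside the global ≥ 20% prevalence
  filter.
* **Quantitative**: restricted to present samples. The abundance is
  transformed to z-standardised log₁₀ relative abundance; the mean/SD used
  (SD with ddof = 1) are stored so validation samples can be scored with
  discovery parameters — the transform is part of the fitted model, not of
  the data. Requires ≥ 10 present samples (`min_present`) and non-zero
  log-abundance variance.
* **Meta**: unweighted Stouffer combination of the signed scores,
  Z = (Z_b + Z_q)/√2, two-tailed normal P. Signed scores are
  Φ⁻¹(1 − P/2) · sign(β); P values are floored at 1e-300 before inversion
  so the inverse CDF stays finite.

The final P is the minimum over computed parts. Exact ties are resolved
meta > quantitative > binary (arbitrary but fixed). Covariates (sex, batch)
are included in both parts by default and can be switched off.

A part that cannot be computed is reported as NaN with a reason, never as
P = 1: folding "untestable" into "tested, null" would bias both the min-P
statistic and the permutation null.

## Permutation FDR

The min-P statistic is anti-conservative under the null (the minimum of
three dependent P values), so q-values are estimated against a permutation
null rather than treating final P values as uniform. The scheme is
Freedman–Lane: the trait is regressed on the covariates once, and per
permutation round the residuals are permuted with one shared sample
permutation across all features, re-attached to the fitted values, and the
whole scan recomputed. Sharing the permutation across features preserves
the across-feature correlation structure that plug-in FDR estimation
assumes. For a threshold t,

    FDR(t) = mean_perm #{P_perm <= t} / max(1, #{P_obs <= t}),

a feature's q-value is the minimum FDR(t) over t at or above its own P,
monotonised to be non-decreasing in P and capped at 1, and the reported
significance threshold is the largest observed P with FDR(t) < α. The
default is 1000 permutations; fewer than 100 is refused (estimates become
unstable) except by explicit override, which exists for exhaustive
brute-force cross-checks on tiny instances.

All of this is vectorised: per feature, the presence vector (and, on its
present-sample subset, the transformed abundance) is residualised against
an orthonormal basis of the covariate design once; each permutation then
costs one dot product per feature per part. The scalar per-feature
functions and the vectorised engine are verified against each other and
against statsmodels OLS in the test suite.

## Pathway association

Predicted pathway abundances (e.g. PICRUSt output; prediction itself is
out of scope) are filtered to terms present in strictly more than 80% of
samples with mean relative abundance strictly above 10⁻⁴; terms labelled
"unclassified" are dropped. Each surviving pathway is tested by univariate
OLS of the trait on its abundance — by default without covariates,
mirroring the plainly univariate convention; a flag enables adjusted runs.
The T statistic (β/SE) is reported alongside P for heatmap use, and the
same residual-permutation FDR machinery calibrates significance.

## Microbial risk score and variance explained

Per repeat, samples are split 70/30 (discovery size = round(0.7·N)); the
two-part scan runs on the discovery set; features with final P ≤ P_t are
selected. The threshold applies to the raw discovery P, not the q-value —
re-running a 1000-permutation FDR inside every one of 100 repeats and six
grid points would be computationally disproportionate, and sweeping the raw
threshold is what the grid is for. A validation sample is scored

    r_m = Σ_j ( β₁_j · b_j + β₂_j · q_j ),

where q_j uses the discovery transform and the abundance term is omitted
when the feature is absent (b_j = 0); a part that was not computable in
discovery contributes nothing. A feature absent from the validation table
altogether contributes nothing. The variance explained is the incremental
R²: R²(trait ~ covariates + r_m) − R²(trait ~ covariates), floored at 0.
This is the semi-partial (not partial) correlation squared; the two differ
by the factor (1 − R² of the covariate-only model), and the incremental
form is the direct reading of "R² corrected for sex and batch". Results
report mean and SD of R² per grid threshold over (default) 100 repeats,
with the grid {1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.1}.

Known properties of this estimator, measured on synthetic data: it is
attenuated relative to the planted truth (weights estimated on ~168
samples; winner's-curse selections add noise at loose thresholds), so the
max-over-grid mean R² typically lands 10–20% below a planted variance
fraction of 0.25; and under a true R² of 0 the floor-at-0 convention leaves
a small positive bias of order 1/n_validation (~0.01–0.02). The package's
own negative control — shuffling samples against phenotypes — collapses
the curve to that floor.

## Synthetic cohorts

The generator emulates the structure of a 240-animal cecal 16S study: two
sexes (113/127 split), a pen/batch structure (default 6 pens), per-feature
prevalence uniform on (0.2, 1], log-normal abundances among present
samples, closure to proportions, and multinomial rendering at 10,000 tags
per sample so every library has exactly the rarefaction depth. Trait
baselines (means/SDs of GLU, TC, TG, HDL, LDL in mmol/L) follow the
emulated cohort's summary statistics; a sex effect of +0.17 mmol/L on LDL
for castrated boars is planted by default, which propagates into LDL/HDL
and AI through their defining identities. HDL is generated on the log scale
(moment-matched lognormal), so it is positive by construction.

Planted microbial effects on the causal trait (default GLU) follow a
deterministic geometric ladder: the k-th causal feature's contribution has
standard deviation `effect_scale · effect_decay^k` in variance-normalised
predictor units, with ranks interleaved across abundance-driven,
presence-driven and both-driven types and random signs. Two choices here
deserve justification:

* **Heavy concentration (decay 0.35 by default).** In cohorts of this size
  the association signal is dominated by a handful of taxa — the emulated
  study recovers ~83% of its maximal explained variance already at its
  strictest selection threshold. A flat effect profile across 30 causal
  features would put every feature below detectability at n = 240 and make
  the generator's stated truth unrecoverable by any method; the ladder's
  top rank carrying ~88% of the planted variance reproduces the observed
  concentration.
* **Exact realisation.** Causal features are drawn only from features that
  pass the default analysis filter and have identifiable prevalence
  (presence effects need mid prevalence; abundance effects enough present
  samples). The residual noise is made empirically orthogonal to the
  planted predictors, and when a target microbiome R² is set the microbial
  part is rescaled so the realised variance ratio on the generated cohort
  equals the target exactly (a quadratic in the scale factor). The truth
  sidecar therefore states effects that hold in the cohort as generated,
  not merely in expectation — without this, realised per-feature variance
  shares fluctuate by ±0.05 across cohorts and recovery checks measure
  cohort luck rather than estimator behaviour.

What the generator does **not** model: phylogenetic correlation structure
among features, sequencing-error and chimera processes, longitudinal
sampling, and genuinely compositional effect confounding beyond what
closure induces. Passing recovery tests on these cohorts therefore shows
the estimator chain is correct and calibrated under the stated model; it
does not certify performance on real data with correlated taxa.

## Numerical and interface choices

* The "≥ 0.05% relative abundance" filter uses the **mean** relative
  abundance across all samples (zeros included); a `max` mode is exposed.
  OTU-filter thresholds are inclusive (≥); pathway-filter thresholds are
  strict (>), following the respective conventions.
* Rarefaction is multivariate hypergeometric (without replacement) per
  sample, seeded; samples below depth are an error unless explicitly
  dropped, and dropped samples are named. The open question of how a
  library slightly under depth should be handled is resolved by refusing to
  guess.
* Shannon diversity uses natural log; Welch's t (not pooled) is the group
  comparison. Both are the safer defaults where the convention is
  ambiguous.
* Aggregation to a taxonomic rank sums abundances over features sharing
  the rank label; features unassigned at that rank collapse into an
  `unassigned` row so column totals are conserved, and that row is excluded
  from association scans by default.
* Degenerate inputs error loudly (all-zero samples, constant vectors,
  HDL ≤ 0 rows get missing derived indices with a warning) rather than
  propagating silent zeros.
* All randomness is numpy `Generator`-based. The CLI derives per-stage
  streams from one top-level seed via `SeedSequence([seed, stage_index])`;
  the CV driver spawns one child sequence per repeat. Fixed seed implies
  bit-identical output throughout.
* Problem sizes used by the shipped checks (cohorts of 240 samples with
  200–500 features, 200–1000 permutations, 100 CV repeats) were chosen so
  the complete validation runs comfortably on a single CPU; they match the
  emulated study's dimensions where those are stated.

## Limitations

The association model is marginal per feature: correlated taxa share
credit, and no compositional (log-ratio) transform beyond the stated
per-feature one is applied. Mixed models for pen effects, phylogeny-aware
tests, and kinship/similarity-matrix variance partitioning are out of
scope. The risk score is additive with independently estimated weights; it
is a prediction heuristic, not a joint model, and its R² should be read as
a lower bound on the microbiome's contribution under the model's
assumptions.
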