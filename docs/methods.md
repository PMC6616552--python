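# Methods

This note documents the statistical procedures the package implements,
the design choices made where several readings were defensible, what the
synthetic cohort generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Study design the pipeline assumes

A longitudinal cohort of up to nine subjects, five of whom collect stool
during flight (the others contribute stool only before and after), sampled
at ten timepoints — four preflight (L-240, L-150, L-90, L-60), three
inflight (FD7, FD90, FD180; FD360 for a twelve-month mission), three
postflight (R+0, R+30, R+60) — at five body sites, plus six station
surfaces swabbed inflight, PCR and extraction-kit negative controls, and a
plasma cytokine panel at five blood sessions (L-60, FD7, FD180, R+0,
R+180). Mission stage is derived from the timepoint prefix (L-/FD/R+).
Timepoints are a closed vocabulary: downstream pairing keys on the labels,
so free-form day offsets are rejected at load. Samples with zero total
reads are rejected because total-sum normalization is undefined for them.

## QC rules, read literally

An OTU is kept when at least 4 samples each carry at least 4 of its reads.
An OTU is a contaminant when any *single* negative-control sample carries
at least 5 of its reads; "either control" is read per control sample, not
as a sum across controls, so 4 + 4 reads in two controls does not trigger
removal. Control columns are dropped after the screen, and skipping the
screen entirely requires an explicit opt-out flag. Normalization is
total-sum scaling; all downstream procedures operate on relative
abundance, so no rarefying of counts is performed for normalization.

The preflight core of a site contains the taxa detected (≥ 4 reads) in at
least 75 % of that site's preflight samples; at genus level, counts are
summed within genus first, and unclassified genera are keyed as
family + " (uncl.)". Station-surface residency is reported under two
readings of the persistence rule — strict (nonzero at every relative
timepoint) and relaxed (no run of two or more consecutive zero
timepoints) — because the two clauses of the rule are mutually redundant
if read literally; strict membership always implies relaxed, and reports
default to strict.

## Diversity

Shannon diversity uses the natural log (the convention of the cited
ecology tooling); rarefied richness is the exact without-replacement
expectation E[Sₙ] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], evaluated via log-gamma
to avoid overflow, with the depth defaulting to the minimum library size
of the compared set and recorded in the output. Weighted Bray-Curtis is
computed on relative abundances; unweighted on the presence pattern
(count > 0) of the filtered table. PCoA is classical scaling of
−½·J·D²·J; eigenvalues are reported including negatives, coordinates are
returned on positive axes only, and each axis is sign-fixed so its
largest-magnitude coordinate is positive (removing the eigenvector sign
ambiguity from plots and tests).

## Mission-stage inference

Alpha-diversity and distance contrasts use a linear mixed model with a
per-subject random intercept fit by REML (statsmodels MixedLM) and Wald
normal inference; a singular or non-convergent fit falls back to OLS and
the record is flagged. Distance designs use within-astronaut sample pairs
only: the within/between-stage comparison pools same-stage pairs of the
two stages under study against their cross-stage pairs, and the
distance-to-baseline trajectory averages each later sample's distances to
all of that astronaut's preflight samples. These pair-level observations
are pseudo-replicated (each sample appears in many pairs); the
mixed-model-on-distances design is reproduced as a faithful-reproduction
choice rather than replaced by a permutation framework.

PERMANOVA is the single-factor distance decomposition with
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), so the smallest attainable p is
1/(n_perm + 1). When strata are given, labels are permuted within strata
only — the conventional reading of "stratifying by body site"; a stratum
entirely in one group contributes no permutation variability and is
warned about. Inter-subject convergence is tested by a Welch t-test on
cross-astronaut distances within each stage, and attributed to genera by
the reduction of the inter-subject coefficient of variation, where the CV
of a genus within a stage is SD/mean of the per-subject *mean* relative
abundance — each subject's replicate samples are pooled first so
within-subject variance does not masquerade as inter-subject dispersion
(the alternative per-sample reading is noted as open). The cumulative
fraction in the ranking is taken over positive reductions, as defined for
the record type; note that with ≤ 5 subjects, CV estimation noise alone
gives many null genera small positive reductions, so attribution claims
about "share of the total reduction" are better made against the net
total (positive and negative reductions summed), which the tests use.

The differential-abundance screen is plumbing, not a reimplementation of
published count-model packages: per OTU, log relative abundance (floored
at half that OTU's minimum nonzero value) is centered within subject, the
statistic is the inflight−preflight mean, the null is built by permuting
stage labels within subject, and BH is applied at the configured level
(default 10 %). An externally produced candidate list bypasses the screen
verbatim.

## Cytokines

Each analyte carries a transform: identity, log, or reciprocal-censored.
The per-analyte transform table of the original assay panel is not
shipped; the registry defaults every analyte to log and the
reciprocal-censored analytes are user-specified. The reciprocal maps a
left-censored concentration (c < L) to a right-censored value
(1/c > 1/L); the regression is then a lognormal MLE with session and
subject fixed effects in which censored observations contribute
upper-tail log-probabilities, optimized by BFGS with an analytic gradient
and Wald standard errors from the finite-difference observed information.
With no censored rows the model is returned as its exact OLS reduction.
Analytes with more than 50 % censored observations (configurable; no
number is canonical) are excluded with a reason. All analyte × session
p-values — four sessions against the L-60 baseline per analyte — enter
one BH step-up, and the realized p threshold is reported alongside
monotone-adjusted q-values.

## The Somers' D association procedure

Relative abundance is discretized to Y = the nearest integer to log₂ RA,
rounding half-integers away from zero (dyadic boundaries are measure-zero
in real data but synthetic data can hit them); RA = 0 maps one level
below the OTU's minimum positive level, computed over the analysis subset
(the five sessions and candidate subjects), the narrower reading of "the
lowest level". This makes only ≥ 2-fold abundance changes register.
Session pairs are formed within subject over sessions where both the
stool sample and the cytokine measurement exist; X is the natural log of
the concentration, with censored values clamped at the detection limit.
Pooled Somers' D counts concordant and discordant pairs across all
subjects jointly (pair-count weighting, not subject weighting):
D = (C − Q)/#{ΔY ≠ 0}; pairs tied on X but not on Y stay in the
denominator.

The SE is a delete-one-subject jackknife — the standard cluster-respecting
resampling estimator; the unnamed "resampling method" of the original
procedure is underdetermined, and this is the conventional choice. The
p-value uses a Student-t reference with g − 1 degrees of freedom for g
contributing subjects rather than a normal: at the 5–9 clusters this
design provides, the normal reference is measurably anticonservative
(about 6 % of null p-values below 0.01 in simulation), while t(g−1)
calibrates to the nominal rate. A combination is excluded *before* any
p-value is computed when it supports fewer than 10 valid comparisons — a
"comparison" read as a subject-session observation with RA > 0 and an
uncensored cytokine (the pairs reading is exposed as a configuration
switch) — when all pairs are tied on Y, when fewer than two subjects
contribute untied pairs, or when the jackknife is degenerate (SE = 0).
BH at 1 % FDR runs across the computed p-values only.

## The synthetic cohort generator

Counts are Dirichlet-multinomial: a per-site mean composition (symmetric
Dirichlet draw), per-subject lognormal intercepts with taxon-specific
scale (uniform between 0.3× and 1× of `subject_effect_sd` = 0.7 ln
units — most taxa moderately subject-specific), a per-(subject,
timepoint) temporal wobble with taxon-specific volatility (uniform
between 0.2 and 0.5 ln units for background taxa; taxa named in cytokine
couplings are pinned to `session_effect_sd` = 1.75 so planted temporal
signal exists), stage fold-changes applied multiplicatively, and a
per-sample Dirichlet draw at concentration 300 over a lognormal library
size (median 20 000 reads by default; the real distribution is not
printed anywhere, so this is configurable). Column sums equal the drawn
library sizes exactly.

Convergence taxa are generated with bimodal carriage: each has one
carrier subject at +3.5 ln above a 0.5 % baseline, and inflight the whole
inter-subject deviation (intercept and wobble) is multiplied by the
convergence factor. This mirrors the empirical pattern in which the
strongly subject-specific gut genera are the ones that converge; uniform
lognormal dispersion instead saturates the small-cohort CV ceiling
(√(n−1)) and makes attribution impossible at any effect size. Station
surfaces mix a resident profile with the concurrent crew's skin
composition (weight 0.7 resident by default) so skin–surface similarity
analyses have signal. Controls carry planted contaminant taxa at 5–60
reads plus sub-threshold noise. Cytokine log-concentrations are a
baseline plus subject intercept, planted session effects, coupling terms
acting on the *latent* (generative) log abundance of stool taxa — not the
realized counts, avoiding circularity while keeping concordance
recoverable — and Gaussian noise; values under an analyte's detection
limit are clamped there and flagged censored. Subjects who opt out of
inflight stool still collect pre- and postflight stool, and stool is also
collected at R+180 to match the last blood session, so up to nine
subjects contribute association clusters.

What the generator does **not** emulate: sequence-level artifacts
(chimeras, primer bias), phylogenetic correlation between taxa,
compositional interactions beyond closure, nearest-date matching of stool
to blood sessions (matching is by exact label), and hormone/virus time
series. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under a faithful abstraction of the design — not
that the pipeline is robust to every artifact of real amplicon data.

## Problem sizes used in the test suite

The statistical acceptance checks run at sizes chosen to make Monte-Carlo
conclusions stable while keeping the suite quick on one CPU: 1 000 random
cohorts for the Somers oracle, 10 000 random abundances for the
discretization guarantees, 1 000 random vectors for the BH oracle, 200
null cohorts for screen calibration, 200 runs × 199 permutations for
PERMANOVA uniformity, 500 simulations for mixed-model coverage and for
censored-regression recovery, and 100 cohorts each for the convergence
and end-to-end recovery checks. Power/recovery checks plant effects of
the magnitude the method is meant to detect (≥ 2-fold discretized
changes, strong couplings of |strength| 1.5 against noise SD 0.2,
inflight drops of several fold); the whole suite runs in a few minutes.

## Known limitations

* Wald inference throughout (mixed models, censored MLE); no
  Satterthwaite or Kenward-Roger small-sample corrections.
* PERMANOVA is single-factor only; multivariate dispersion is not tested
  separately, so location and dispersion effects are confounded as in any
  PERMANOVA.
* The Somers screen's t(g−1) reference is itself an approximation; with
  very few clusters the jackknife SE remains noisy, which is exactly why
  the ≥ 10-comparison exclusion rule exists.
* Distance-design mixed models treat pseudo-replicated pair distances as
  observations (by design, for faithfulness).
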