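# Methods

## The task and its staircase

The Filter Detection Task is modelled as one decision event per trial: a
condition (resistance vs sham), a yes/no response and a 1–10 confidence
rating. Conditions are pseudo-randomised in blocks of ten (five of each,
shuffled), so any contiguous completed block in a log is balanced. Breathing
physiology (baseline breaths, airflow, pressure) is out of scope; the filter
count is an abstract intensity unit.

The staircase tracks, per filter level, the number of correct responses k out
of n trials, pooled over both conditions (hits plus correct rejections — task
performance is a single accuracy). Accuracy at the current level carries a
uniform Beta(1, 1) prior, hence a Beta(k+1, n−k+1) posterior. After every
trial the posterior mass inside the target band [0.65, 0.80] is evaluated;
if it falls below 0.20 the level moves in the direction indicated by a point
estimate of accuracy (posterior mean (k+1)/(n+2) by default; the MLE k/n is
available by configuration). Tallies persist across level changes: returning
to a level resumes its count, and the session stops at the first moment any
level holds 60 trials.

Choices the task description leaves open, surfaced as configuration with
these defaults:

| parameter | default | rationale |
|---|---|---|
| prior on accuracy | Beta(1, 1) | minimal assumption behind "beta CDFs" |
| evidence floor before a move | 5 trials at the level | a fresh level carries band mass 0.15 < 0.20 under the prior alone, which would otherwise force an immediate move |
| start level | 4 filters | near the cohort-mean threshold (~3.7 filters) |
| level bounds | 1–12 | physical stacking bound; a removal at level 1 clamps to "stay"; persistent failure at level 12 completes with `validity_flag=False` |
| safety cap | 400 total trials | a session that never settles returns `completed=False`, never a silent truncation |

With the five-trial floor the trigger is deliberately permissive: five
consecutive correct answers (probability 0.19 at 72% accuracy) already
satisfy it, so even in-band observers change level in roughly half of
sessions. This matches the task's observed behaviour of ~73 ± 14 total trials
for 60 analysed.

## Generative observers

Observers are equal-variance SDT deciders: at f filters the evidence is
N(−d′(f)/2, 1) under sham and N(+d′(f)/2, 1) under resistance, with
d′(f) = slope·f and a fixed criterion c. The slope is set so unbiased
accuracy at the subject's threshold filter count equals 75% (the band
centre): slope = 2·z(0.75)/is_filters. Sham trials always draw from the
stimulus-absent distribution — the sham filter is empty, whatever the current
level. A small lapse rate (default 1%) answers and rates uniformly.

Confidence is generated from the same type-2 likelihood later fitted (a
self-consistent model, making parameter recovery well-posed): given the
response, the rating is drawn from the response-conditional distribution of a
second SDT observer with sensitivity meta-d′ = Mratio·d′, type-1 criterion
scaled as c′ = c·Mratio, and nine type-2 criteria per response at
c′ ± s·0.25·(1..9). The scale s is solved per subject (bisection) so the
expected mean confidence at the threshold level equals the subject's
metacognitive-bias trait; the solution is clamped at the scale bounds when a
target near 1 or 10 is unreachable.

## Cohort generator

Traits are drawn through a Gaussian copula: latent multivariate-normal scores
with the target correlation matrix (validated symmetric, unit-diagonal, PSD)
are pushed through each trait's quantile function. Marginals are truncated
normals whose *parent* location/scale are moment-matched numerically so the
truncated distribution delivers the configured mean and SD despite instrument
bounds (GAD-7 0–21, confidence 1–10, filters ≥ 1); integer instruments are
rounded, which adds variance 1/12 and attenuates target correlations by a few
percent — within the ±0.06 fidelity the tests enforce at n = 2000.

Defaults: GAD-7 2.85 ± 2.49; filters at threshold 3.69 ± 1.84; decision bias
0.09 ± 0.33; metacognitive bias 6.22 ± 1.37; MAIA 3.2 ± 0.6 and PANAS-P/N
32 ± 7 / 16 ± 5.5 (instrument-typical community values; only their
correlations with metacognitive bias are constrained: +0.30 and +0.37/−0.22).
Planted correlations additionally include GAD-7 × metacognitive bias −0.26 and
GAD-7 × filters +0.27. Generative Mratio is lognormal with median 0.84 and
log-SD 0.25: the 0.84 ± 0.05 group summary such studies report is
posterior-shrunk, so 0.05 would understate the between-subject spread and
make recovery studies degenerate.

## Hierarchical meta-d′ estimation

Per subject the analysed trials are tabulated as rating counts indexed by
stimulus × response × confidence bin. Ratings are grouped into B = 4 bins
(edges {1–3, 4–5, 6–8, 9–10}) by default to avoid sparse 10-bin multinomials
at 60 trials; B = 10 is supported. The model:

- log Mratio_s ~ Normal(μ, σ); μ ~ Normal(0, 1); σ ~ HalfNormal(1);
- meta-d′_s = Mratio_s · d′_s with d′_s, c_s fixed point estimates from the
  type-1 stage (the two-stage scheme: meta-d′ is referred to the subject's
  measured d′);
- subject type-2 criteria are free, parameterised as log-increments from the
  scaled criterion c′_s = c_s·Mratio_s (ordered by construction), each
  increment with a weakly-informative Normal(log 0.4, 1) prior on the log
  scale;
- response-conditional rating probabilities are Gaussian-area ratios; the
  counts are multinomial within each stimulus × response cell.

Sampling is Metropolis-within-Gibbs, vectorised across subjects:
coordinate-wise random-walk proposals on each subject block plus a joint
(Mratio, criteria) proposal along their posterior ridge; a conjugate Gibbs
draw for μ; an exact slice-sampling update of σ's conditional; and two global
moves that cross the hierarchical funnel — a translation of μ together with
all log Mratio_s, and a rescaling of σ together with the subject deviations.
Proposal scales adapt during warmup only (1000 warmup + 1000 kept draws per
chain, 3 chains by default). Split-chain R-hat and ESS are computed with
arviz over μ, σ and all log Mratio_s; summaries always carry an explicit
`converged` flag (threshold R-hat ≤ 1.05) rather than failing silently.
Subjects whose ratings are constant within every used response class are
flagged but retained. Degenerate d′ ≤ 0 (chance performers) is rejected:
Mratio is undefined there, and the pipeline excludes such subjects from the
fit while keeping their type-1 measures.

Finite-sample behaviour, measured by the recovery studies in
`analysis/05_validation_studies.py`: with known type-1 parameters the group
posterior mean recovers generative medians of 1.0 and 0.8 well within ±0.15
at 30 subjects × 60 trials; feeding 60-trial *estimated* d′/c instead adds
roughly 0.26 SD of log-scale noise per subject, inflating σ̂ and biasing the
group mean down by ~8–10%. The recovery studies therefore condition on the
generative type-1 values (the standard recovery design), while the pipeline
on "data" uses estimated d′/c as an analysis of real logs would have to.
Recovery runs use longer chains (1500 warmup + 2000 draws) purely for
diagnostic headroom.

## Behavioural statistics

Pearson correlations are computed pairwise on complete observations with
two-tailed p-values from the t-transform on n − 2 df; constant columns yield
explicit missing values. The Benjamini–Hochberg family is the set of unique
off-diagonal pairs of one matrix. Correlations involving the filter count are
annotated as inverse-scaled (more filters = lower sensitivity). The power
calculation uses the noncentral F with λ = f²·n and numerator df = number of
predictors; for f² = 0.15, α = 0.05, one predictor the exact convention gives
a minimal n of 55 (power at 54 is 0.7976), while the common rounded-λ
software convention reports 54 — both documented rather than adjudicated.

## Connectivity inference

Volumes are voxel-index grids with no affine or registration semantics (those
belong to external preprocessing tools). The simulator gives both seed
regions a shared latent time series (temporally smoothed, standardised white
noise) plus i.i.d. voxel noise; target voxels follow β_s × latent + noise
with β_s = baseline + effect × (covariate_s − mean); all other voxels are
pure noise. It does not emulate scanner drift, physiological aliasing or
spatial autocorrelation of real fMRI noise, so the calibration results
demonstrate correctness of the inference chain, not robustness to realistic
noise.

First level: per-voxel OLS of the series on [intercept, seed mean series,
backward-difference temporal derivative]; the reported β/z refer to the seed
regressor. Fixed effects across hemisphere seeds: inverse-variance weighted
mean plus L−R and R−L differences (zero-variance voxels fall back to an
unweighted average). Group level: OLS per voxel on gender-split designs —
male/female intercepts and the measure demeaned within each gender (zero
elsewhere), optionally plus gender-split GAD-7 covariates; contrasts are the
positive/negative measure main effect and the gender interaction. Group
variance weighting by first-level variances is deliberately omitted (plain
OLS on the fixed-effects maps).

TFCE integrates extent^0.5 × height² over thresholds in steps of dh
(default: peak/100, right Riemann sum, 26-connectivity); negative-direction
inference enhances the negated map. Permutation inference uses the
Freedman–Lane scheme: the design is rotated so the contrast is a single
interest regressor, reduced-model residuals are row-permuted and the
reduced-model fit added back, and the per-voxel FWE p-value is the plus-one
estimator against the permutation distribution of the image-wide maximum
TFCE score. When fewer distinct permutations exist than requested, the group
is enumerated exhaustively with a notice. Each permutation's TFCE uses its
own peak-scaled dh, matching the observed map's treatment.

Calibration at desk scale (10×10×6 grids, two 8-voxel seeds, 8-voxel target,
60 timepoints, 500 permutations): the family-wise false-positive rate over
200 effect-free cohorts of 20 subjects stays within 0.05 ± 0.03, and a
coupling effect of 0.5 per covariate unit at n = 40 is detected inside the
target in ≥ 90% of cohorts. The analysis driver uses a 24×24×12 grid with
3³-voxel seeds and 120 timepoints.

## Orchestration and reproducibility

A single master seed fans out to stage seeds (cohort, sessions, MCMC,
volumes, permutations) via `numpy.random.SeedSequence` spawning, so stages
are independently reproducible and share no hidden RNG state. The pipeline
writes TSV/CSV/JSON outputs, a Markdown report and a SHA-256 manifest;
re-running a config reproduces every hash. Configs are validated before any
stage runs, with unknown keys rejected by name.

## Known limitations

- The synthetic volumes' white-noise model understates real fMRI false-positive
  pressure; TFCE/FWE calibration here is a correctness check only.
- The confidence generator and fitter share one model family; an
  evidence-plus-noise generative alternative would probe misspecification and
  is not implemented.
- The hierarchical fit treats d′/c as known; propagation of type-1 uncertainty
  is out of scope, and its finite-sample consequences are quantified above
  rather than corrected.
- Binning confidence to 4 bins discards some type-2 information at 60 trials;
  10-bin fits are supported but sparser.
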