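# respimeta

Simulation and analysis code for studying **respiratory interoception** — how
well people perceive added resistance to their own breathing — and its link to
trait anxiety and brain connectivity. The package re-implements, end to end on
synthetic data, the computational chain of a breathing-perception study:

1. **Filter Detection Task (FDT) staircase.** A yes/no detection task: on each
   trial the participant breathes either through a stack of resistance filters
   or a sham (empty) filter, answers "resistance: yes/no", and rates confidence
   on a 1–10 scale. An adaptive staircase holds accuracy in a 65–80% band: after
   each trial the posterior on accuracy at the current filter number is
   Beta(k+1, n−k+1) (uniform prior on k correct of n), and when the posterior
   mass inside [0.65, 0.80] drops below 0.20 a filter is added (estimated
   accuracy < 0.65) or removed (> 0.80). A session stops once 60 trials
   accumulate at a single filter level; those 60 trials are analysed.

2. **Interoceptive measures.** From the 60 analysed trials: sensitivity
   d′ = z(H) − z(F) and decision bias c = −(z(H) + z(F))/2 (c > 0 = tendency to
   under-report resistance); metacognitive bias = mean confidence; and
   metacognitive insight **Mratio = meta-d′/d′**, where meta-d′ is the SDT
   sensitivity implied by the confidence ratings. Because 60 trials is little
   data for meta-d′, Mratio is estimated hierarchically: log Mratio_s ~
   Normal(μ, σ) across subjects, with a multinomial type-2 likelihood per
   subject and MCMC sampling (custom Metropolis-within-Gibbs; R-hat/ESS via
   arviz).

3. **Behavioural statistics.** Pairwise Pearson correlations with two-tailed
   p-values, Benjamini–Hochberg FDR adjustment, and the recruitment power
   computation (noncentral F, λ = f²·n).

4. **Seed-based connectivity.** On synthetic 4D volumes: mean seed time series
   (masks thresholded at 90% probability) regressed voxel-wise together with
   their temporal derivative; left/right-seed maps combined by fixed effects;
   a group GLM with gender-split demeaned explanatory variables (± a GAD-7
   covariate); and inference by Freedman–Lane permutation with threshold-free
   cluster enhancement (TFCE, E = 0.5, H = 2) and FWE correction from the
   max-statistic null.

Real participant data for such studies are not generally public, so the
package ships a first-class **synthetic-data generator**: a Gaussian-copula
cohort sampler with configurable marginals and correlations, generative SDT
observers whose confidence comes from the same meta-d′ model later fitted,
and a volume simulator with seed/target coupling driven by a subject-level
covariate. Everything is reproducible bit-for-bit from integer seeds.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 7 --out results/cohort
python analysis/02_interoceptive_measures.py --seed 7
python analysis/03_behavioural_statistics.py
python analysis/04_connectivity.py --seed 7 --n-perm 500
```

The first script draws a 65-subject cohort (32 F / 33 M) and runs one
staircase session per subject:

```
cohort written: results/cohort/cohort.tsv (65 subjects)
  GAD-7 mean 2.77 (SD 2.23)
  filters at threshold 4.00 (SD 1.96)
  metacognitive bias 6.08 (SD 1.32)
sessions: mean total trials 75.1 (SD 19.1); mean final level 3.62
```

GAD-7 near 2.85 and ~3.7 filters at threshold are the cohort conditions the
generator is calibrated to; total trials around 75 reflect the staircase
walking to each observer's threshold before the 60-trial stop. The second
script computes the measures and fits the hierarchical model:

```
measures written: results/measures/measures.tsv
  mean d' 1.37, mean c 0.22
  mean confidence 6.06
  group Mratio 0.842 (95% CI 0.72-0.96), max R-hat 1.021, converged: True
```

The group Mratio recovers the generative median (0.84); this cohort draw
happens to sit high on decision bias (generative mean 0.198 for this seed),
which the estimator tracks faithfully. The third script prints the
correlation matrix — here the planted GAD-7 × metacognitive-bias correlation
comes out at R = −0.36 (p = 0.003, surviving FDR in this draw; at the
generative −0.26 it hovers near the significance boundary at n = 65) — plus
the specificity correlations (metacognitive bias × MAIA R = +0.30,
× PANAS-P R = +0.43, × PANAS-N R = −0.06) and the power computation (n = 55
for 80% power at f² = 0.15 under the exact noncentral-F convention; 54 under
the rounded-λ convention). The fourth script reports, for designs with and
without the GAD-7 covariate, the voxels reaching FWE p < 0.05:

```
[measure_only] significant voxels at FWE p<0.05: 48 (48 of 48 target voxels); min FWE p = 0.0020 over 500 permutations
[measure_plus_gad7] significant voxels at FWE p<0.05: 50 (48 of 48 target voxels); min FWE p = 0.0020 over 500 permutations
```

All 48 planted target voxels are recovered; the two extra voxels in the
covariate design are cluster-adjacent spillover from the enhancement step.

`python analysis/05_validation_studies.py --fast` runs scaled-down versions of
the validation studies (staircase band, Mratio recovery, FWE calibration,
detection power).

A single-command pipeline over all stages, with config validation, a Markdown
report and a hash manifest, is available via `respimeta.workbench`:

```python
from respimeta import workbench
report = workbench.run_pipeline(workbench.validate_config("run.yaml"))
```

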