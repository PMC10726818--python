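# gradreveal

Model-based analysis of neural evidence accumulation in **gradual-reveal
fMRI** experiments, with a matched synthetic-data generator so every
stage can be validated by parameter recovery.

## The scientific problem

In a gradual-reveal paradigm an occluded image is slowly unmasked over
25 s while the participant decides, self-paced, which category it
belongs to. Stretching the decision lets slow BOLD sampling (here
TR = 0.42 s) resolve activity *before* versus *after* the moment of
decision. Regions whose activity ramps up from trial onset and peaks at
the decision time behave like neural **evidence accumulators**, and the
profile can be read through drift-diffusion theory:

- **drift rate** `v` — the rate of evidence accumulation, measured as
  the slope of the region's activation profile from its minimum within
  the first 5 trial seconds to its maximum within ±3 s of the
  condition's mean decision time;
- **decision threshold** `a` — the amount of evidence required to
  commit, measured as the peak profile magnitude near the decision
  time (with trial exclusion rules for negative or early maxima);
- for regions that do not accumulate (an amygdala-like step profile, a
  sensory ramp), shape-agnostic **areas under the curve** over the
  pre-decision, post-decision, and full-reveal windows, optionally per
  scan block (three runs each) to resolve habituation.

The pipeline goes from per-ROI BOLD series + BIDS-style event tables +
confound tables to per-subject condition profiles and tidy metric
tables, then to group statistics (paired *t*-tests, repeated-measures
ANOVAs with subject as random factor, Bonferroni-corrected pairwise
comparisons):

1. nuisance regression against the confound table, per-run linear
   detrending and z-scoring (`gradreveal.extract.regress_confounds`);
2. correct-trial filtering and a 5-s hemodynamic shift (12 samples),
   then epoching into a variable-length pre-decision segment and a
   fixed 10-s (24-sample) post-decision segment (`epoch_trials`);
3. linear interpolation of each trial's pre-decision segment onto a
   common per-condition grid set by the condition's mean response time,
   zero-locking, and FIR estimation (one coefficient per time bin,
   ordinary least squares) of the condition profile
   (`gradreveal.profiles`);
4. profile metrics (`gradreveal.metrics`) and group statistics
   (`gradreveal.stats`).

Because self-paced response times couple to the generating parameters
through `RT = a / v`, the bundled generator (`gradreveal.synth`) ties
behaviour, four neural profile archetypes (accumulator,
moment-of-decision, sensory, step), HRF convolution, AR(1) noise and
nuisance structure to known ground truth — so recovery of `v` and `a`
is an executable test of the whole pipeline.

## Worked example

```bash
cat > demo.yaml <<'YAML'
seed: 1
n_subjects: 12
paradigm: {n_runs: 9, n_trials_total: 80}
ground_truth:
  drift_rate: {neutral: 0.083, high: 0.0795}
  threshold: {neutral: 1.0, high: 1.1}
  habituation_factor: 0.5
YAML
gradreveal run-all --config demo.yaml --out demo-run
```

This simulates 12 subjects with a high-salience condition that has a
*shallower* drift (0.0795 vs 0.083 z/s) but a *higher* threshold (1.1
vs 1.0 z), analyses them end to end, and writes `demo-run/metrics.tsv`,
`demo-run/stats/report.md` and profile figures. The report from this
exact configuration reads (excerpt):

```
- accumulator drift rate: condition F(1, 11) = 3.22, p = 0.1004
  - loc drift rate: t(11) = -1.79, p_bonf = 0.1004 (mean diff -0.012)
- accumulator decision threshold: condition F(1, 11) = 3.25, p = 0.09888
  - loc decision threshold: t(11) = 1.80, p_bonf = 0.09888 (mean diff +0.141)
- amygdala AUC period: F(1, 11) = 2696.14, p = 1.663e-14
- occ_pole reveal AUC: t(11) = 5.24, p = 0.0002786 (mean diff +2.136)
- behaviour: RT high - neutral = +1.42 s, t(11) = 8.13, p = 5.588e-06
```

Reading the numbers: the high-salience condition slows decisions by
1.42 s (the distractor effect); the recovered accumulator slope is
shallower for high salience (−0.012 z/s) while the recovered peak is
higher (+0.141 z), matching the generating parameters in direction; the
step-profile region shows a massive post- vs pre-decision AUC
difference; and the sensory region accumulates more area under high
salience. At n = 12 the accumulator contrasts are directional but not
significant — the parameter-recovery studies below use larger designs.

The same stages are available stepwise (`gradreveal simulate`,
`extract`, `profile`, `metrics`, `stats`) and as library functions
(`gradreveal.pipeline.analyze_subject`, `run_experiment`).

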