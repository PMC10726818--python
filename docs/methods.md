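# Methods

This note documents the models, defaults and numerical choices behind
`gradreveal`, what the synthetic generator does and does not emulate,
and the package's known limitations.

## Paradigm and sampling model

A trial consists of a gradual reveal of up to 25 s, a self-paced
decision response during the reveal, a fixed 10-s post-decision period,
and a jittered inter-trial interval drawn uniformly from {6, 8, 10} s.
Runs last 360 s and are sampled at TR = 0.42 s (857 samples/run);
subjects complete 6–9 runs and at most 100 trials. Trials are packed
into runs in order; a trial that would overflow the current run starts
the next run, and trials that do not fit before the last run ends are
dropped (so completed trial counts vary by subject, as they do in
self-paced designs).

Index arithmetic uses round-half-up throughout: the 5-s hemodynamic
shift is `round(5/0.42) = 12` samples (5.04 s), the 10-s post-decision
window is `round(10/0.42) = 24` samples for every trial.

## Behavioural model

Response times couple to the neural parameters through

```
RT = threshold / drift + eps,   eps ~ N(0, rt_noise_sd^2),
```

truncated to (0, 25] s by redrawing (no probability mass piles up at the
edges). Defaults place the neutral condition at a 12.05-s mean RT
(threshold 1.0 z, drift 1.0/12.05 z/s) and the high-salience condition
at 13.83 s (threshold 1.1 z, drift 1.1/13.83 z/s) — i.e. the high
condition combines a *shallower* drift with a *higher* threshold, and
its decisions are slower. `rt_noise_sd` defaults to 3 s, the scale of
between-trial RT variability in self-paced categorization;
configurations whose mean RT reaches the reveal duration are rejected.
Accuracy is Bernoulli(0.93) per trial; only correct trials enter the
analysis. Condition order is randomized per subject with a balanced
50/50 split of the trial list (an assumption; per-condition counts
after correctness filtering are not part of the design).

## Neural profile archetypes

Per trial, on a grid at the TR from onset to RT + 10 s:

- **accumulator** — linear ramp from 0 to the threshold over [0, RT],
  linear decay back to 0 over the 10-s post-decision period. The apex
  is snapped to the grid point nearest RT so that the noiseless peak
  equals the threshold exactly on the sampling grid.
- **moment of decision** — Gaussian bump centred at RT, width 0.75 s
  (narrow relative to the reveal, wide enough to survive HRF smoothing).
- **sensory** — saturating exponential toward the threshold while the
  stimulus is revealed (time constant = a quarter of the reveal), held
  afterwards.
- **step** — 0 before RT, constant threshold-amplitude during the 10-s
  post-decision period. Step amplitudes are attenuated multiplicatively
  per scan block (`factor^(block-1)`, blocks = three consecutive runs),
  emulating amygdala habituation to repeated salient stimuli.

## BOLD synthesis

Neural signals are convolved per run with a double-gamma kernel
(32-s support, normalized to unit sum so slowly varying signals pass
with unit gain and amplitudes survive convolution). The positive lobe
has mode 5.2 s and spread 1.0 s, with a 10% undershoot at 15 s. The
mode was calibrated once, on the noiseless pipeline, so that the
latency the kernel adds to a ramp-to-peak signal matches the fixed
12-sample shift the extraction stage removes: with this kernel the
decision-locked peak of a noiseless accumulator lands within one grid
bin of the true decision time for RTs across the paradigm's range
(8–14 s). A kernel whose effective latency differed from the shift
correction would bias every timing metric by the difference.

Noise is additive per ROI: stationary AR(1) (coefficient 0.3, marginal
sd `noise_sd`, default 0.5 z), a random low-frequency cosine drift
(3 components per run, amplitude sd 0.3), and a global signal component
shared across ROIs (slow AR(1), amplitude 0.2). The generator also
emits the confound table an fMRIPrep-style preprocessing would provide:
the global signal with derivative and quadratic expansions plus the
per-run cosine basis. All randomness flows from one root
`numpy.random.SeedSequence` with per-subject spawned substreams;
identical seeds give bit-identical events and series.

What the generator does **not** emulate: image-space stimuli, eye
movements or attention, valence as a separate dimension, spatial
structure within ROIs, motion artefacts (the analysis assumes
ICA-AROMA-style denoising already happened), and physiological noise
spectra beyond AR(1). Passing recovery tests therefore demonstrates the
pipeline's correctness under this noise model, not performance on real
scanner data.

## Extraction

Per run: confound columns are standardized, an intercept is added, and
the least-squares fit is removed (rank-deficient confound matrices are
solved by SVD with a logged warning); residuals are linearly detrended
and z-scored per ROI per run. Z-scoring and detrending are per run
rather than across concatenated runs — per-run matches run-wise
extraction and guards against inter-run offsets; ROIs whose residuals
are numerically constant are flagged and zeroed rather than amplified.
Epochs are cut per trial after shifting indices by 12 samples: the
pre-decision segment spans shifted onset to shifted response (variable
length, ≥ 2 samples), the post-decision segment exactly 24 samples.
Epochs never cross run boundaries; trials whose shifted post window
would pass the run end are dropped with a logged reason.

## Common grid, zero-locking, FIR

The common pre-decision grid length per condition is
`round(mean correct RT / TR)`, computed per subject (self-paced
behaviour makes subject-level grids the natural choice; group-level
grids can be supplied explicitly for figure-style averaging). Each
trial's pre-decision segment is linearly resampled onto that many
equally spaced points (endpoints preserved); the post-decision segment
is appended unchanged; the trial is zero-locked by subtracting the
value at the first grid point (the literal reading of "begins at
zero"; baseline-mean subtraction is the obvious alternative and its
variance consequences are discussed under limitations). The FIR model
has one indicator regressor per grid bin, stacked across trials, solved
with `numpy.linalg.lstsq`; on this design the solution equals the
pointwise trial mean, which is asserted as an identity in the tests.

## Metrics

- **Slope (drift rate)**: computed on the condition FIR profile, from
  the minimum coefficient with time in [0, 5] s to the maximum within
  ±3 s of the condition mean decision time (windows snapped to nearest
  bins, endpoints inclusive, ties to the earliest bin). A peak time at
  or before the minimum time marks the metric invalid rather than
  returning a silent zero.
- **Peak magnitude (decision threshold)**: computed per trial as the
  maximum within the ±3-s peri-decision window, then averaged over
  included trials. A trial is excluded when its global maximum is
  negative ("negative-maximum") or occurs within the first 5 s of the
  reveal ("early-peak"); every exclusion is logged with subject, ROI,
  trial and reason. The slope-on-profile / peak-per-trial asymmetry is
  deliberate; the ±3-s window is a parameter (default 3 s).
- **AUC**: signed trapezoidal integral of the profile over
  [0, mean RT], [mean RT, grid end], and [0, min(25 s, grid end)];
  signed integration keeps AUC additive over adjacent windows.
- **Blockwise**: runs are grouped into blocks {1–3}, {4–6}, {7–9}
  (> 9 runs is an error; a final partial block is kept with a warning);
  FIR and AUC are recomputed within block from the session-grid trials.

## Group statistics

Paired *t*-tests are classical two-sided tests with a degenerate flag
for zero-variance differences (all-equal inputs report t = 0, p = 1).
Repeated-measures ANOVA (1–3 within factors) tests each effect against
its own effect × subject interaction mean square (statsmodels
`AnovaRM`); replicates in a cell are aggregated by the mean and
subjects with missing cells are dropped listwise with a warning. On a
2-level single-factor design the ANOVA reproduces the paired *t* via
F = t². No sphericity correction is applied by default. Bonferroni
adjustment is `min(1, m·p)`. A calibration harness simulates no-effect
experiments through the full pipeline and checks that the condition
test rejects at the nominal rate.

## Verification studies and problem sizes

`gradreveal.validation` defines the self-validation studies run by
`scripts/acceptance.py` and the acceptance tests: the FIR/mean identity
(40 trials × 53 bins), the interpolation oracle (1000 random trials
against an independent piecewise-linear evaluator), parameter recovery
(100 experiments × 20 subjects × ~40 correct trials/condition, drifts
0.10/0.07 z/s, thresholds 1.0/1.2 z, noise 0.5 z), null calibration
(500 no-effect experiments of 10 subjects), the exclusion-rule toy set,
noiseless peak timing (RTs 8/10/12/14 s), and the step-profile
habituation study (100 simulations of 35 subjects — the cohort size of
the blockwise analysis this study emulates — at habituation factor
0.5). These sizes keep the full suite around five minutes on one CPU.

## Known limitations

- **Absolute amplitude is only partially recoverable after
  z-scoring.** Standardizing residuals per run divides out a scale that
  includes the signal's own variance. Within a subject the condition
  contrast survives (both conditions share runs), and direction is
  recovered essentially always; but across subjects the recovered peak
  magnitude compresses (about half the generating amplitude slope
  survives at the default signal-to-noise) and carries measurement
  noise of ~0.15 z per subject × condition at 40 trials. Cross-subject
  rank correlation between generating and recovered *thresholds*
  therefore plateaus around 0.65–0.75 under these conditions — a
  property of the standardization, not of the estimator: removing
  standardization entirely raises the separation only marginally
  (the residual floor is peak-measurement noise at 40 trials/condition).
  Drift-rate rank recovery is materially better (~0.85) because the
  slope pools information over the whole ramp.
- **Zero-locking injects single-bin noise into integrals.** Subtracting
  the first-bin value propagates that bin's noise into every downstream
  AUC (≈ window length × offset noise), which is the limiting noise for
  blockwise AUC contrasts. Baseline-mean subtraction would reduce it at
  the cost of redefining the zero point.
- The HRF is narrower than canonical kernels; it is an instrument
  choice matched to the fixed shift correction (above), not a
  physiological estimate.
- Under geometric habituation a genuine half-sized effect remains in
  the middle scan block, so "the condition difference is present only
  in block 1" is operationalized as: block-1 difference positive,
  significant, and exceeding the block-3 difference.
- The ANOVA layer reports classical repeated-measures denominator
  degrees of freedom; conventions that pool error terms across cells
  produce different (larger) denominators and are not emulated.
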