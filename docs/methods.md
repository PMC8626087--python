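# Methods

`attnet` re-implements, as a tested library, the analysis pipeline of a
multi-session neurostimulation + attention-training study design: adaptive
psychophysical thresholding, cross-task training sessions, censoring-aware
resting-state fMRI preprocessing, seed-based functional connectivity of a
10-region attention network (DVAN) against a 10-region default-mode control
network (DMN), the repeated-measures statistical battery, and an FIR
deconvolution GLM for task runs.  Because the package is exercised on
synthetic data with known ground truth, every stage is paired with a
generator that states the world the analysis assumes.

## Synthetic world

**Cohort.** Three stimulation groups (Parietal, hMT+, Sham) × 10 subjects ×
2 fMRI sessions; resting runs of 120 volumes at TR = 2.0 s.  Group
assignment is a seeded random permutation.

**ROI BOLD series.** Multivariate Gaussian innovations with a target
correlation matrix C imposed via its eigen-factorization, then colored by an
identical AR(1) recursion per region, x_t = φ x_{t−1} + e_t.  Because every
region shares φ, the stationary cross-correlation of the colored series
equals C exactly; series are rescaled to unit marginal variance times
`noise_sd`.  Defaults: φ = 0.4 (a typical lag-1 autocorrelation for BOLD at
TR = 2 s) and a uniform within-network correlation r = 0.3 (a realistic
within-network resting coupling).  A 50-frame burn-in removes transients.
Not modeled: hemodynamic convolution, physiological noise, scanner drift
beyond a linear trend — so green recovery tests establish correctness of the
estimators under the pipeline's own assumptions, not robustness to every
real-data artifact.

**Connectivity effects.** A stimulation effect is a Fisher-z increment
`delta_z` (default 0.3) added to every unique within-network edge of the
target network, for the target group in session 2 only.  If the implied
correlation matrix leaves the PSD cone it is repaired by eigenvalue clipping
with diagonal re-normalization, and the achieved post-repair increment is
the recorded ground truth (`achieved_delta_z`).

**Motion.** A random-walk drift (per-frame sd 0.02 mm; rotations scaled to
0.002 rad) plus Bernoulli spikes of configurable amplitude at known frames;
the spike list is returned as ground truth for censoring tests.

**Observers.** Cumulative-Gaussian psychometric function
Ψ(x) = Φ((x − pse)/slope) with Ψ(pse) = 0.5; the reported-'different'
probability is `guess + (1 − guess − lapse)·Ψ(x)` on different trials and
the same model at offset 0 on same trials.  Units are degrees (orientation
discrimination, OD) or milliseconds (temporal-order judgment, TOJ).

**Behavior.** Accuracy trajectories follow a linear drift in logit-accuracy
per training day, from a 0.5 baseline (tasks run at threshold).  Default
total pre-to-post changes are the study's stated world: OD +29.8 / +2.2 /
−3.1 percentage points and TOJ +3.1 / −4.1 / −7.8 for Parietal / hMT+ /
Sham; per-subject offsets are Gaussian in logit space (sd 0.15) and observed
accuracies are binomial over 120 trials.

## Thresholding

A 3-down-1-up staircase on different-type trials: one error eases the task
by one step, three consecutive correct responses harden it, termination at
30 direction reversals (cap 400 trials).  Start level and step size are not
design constants of the original procedure, so they are configurable
(defaults 8.0 and 0.5 stimulus units).  Two threshold read-outs:

- `reversal_mean` — mean of the last 8 reversal levels.  This is the
  staircase's own convergence point, which for a 3-down-1-up rule sits at
  the ~79.4% correct level (p³ = 0.5), i.e. `pse + slope·Φ⁻¹(0.794)`.
- `pse_fit` (default) — maximum-likelihood cumulative-Gaussian fit to the
  full trial log, read out at its 50% point.  This is the point of
  subjective equality the procedure is defined to deliver: presenting
  different-type trials at this level yields ~50% 'different' responses,
  which the 15 validation trials check against a configurable band.

Monte-Carlo calibration (200 runs, pse = 2, slope = 1): reversal_mean
converges to 2.82 (analytic 79.4% point 2.823) and pse_fit to 2.07.  The
small (~3%) upward bias of the ML read-out is a finite-sample effect of the
staircase's asymmetric sampling around the 79% level and is left as is.

Sessions interleave the two tasks randomly within blocks: 120 standard
trials per task (same/different truth balanced, test side left/right
balanced) in 4 blocks, plus 6 easy catch trials per block (≈20° / ≈150 ms)
— 240 standard + 24 catch per session.  Scoring flags subjects whose catch
accuracy is not significantly above chance (one-sided binomial test).

## Preprocessing

Canonical order, enforced and recorded in each run's provenance:
drop initial volumes (4) → nuisance regression → detrend →
spectral interpolation → band-pass → censor removal.

- **Nuisance regression**: intercept + 12 motion regressors (6 realignment
  parameters and their backward-difference derivatives, first frame 0) + a
  ventricle signal; least squares with greedy removal of collinear columns.
- **Censoring**: framewise displacement FD = Σ|Δtrans| + 50 mm·Σ|Δrot|
  (rotations in radians); frames with FD > 0.5 mm are scrubbed (the
  frame-level threshold is a declared pipeline default, configurable).  A
  run is discarded outright when any single-frame change in any of the six
  dimensions exceeds 3 mm.
- **Interpolation (least-squares spectral fit)**: a sine/cosine basis at
  oversampled Fourier frequencies (oversampling 8, spacing 1/(8·T), up to
  half Nyquist) is fit jointly to retained frames with a ridge penalty of
  1e-3 · n_retained on the normal equations; censored frames take the
  prediction, retained frames are untouched.  Basis columns near Nyquist are
  excluded (nearly degenerate on a regular grid) and predictions are clamped
  to the retained data's per-ROI range: with boundary or clustered censored
  frames an unconstrained fit can swing to tens of times the data scale, and
  the filter then spreads that artifact into retained neighbors, driving all
  edges toward |r| ≈ 1.  The filled frames exist only so the band-pass sees
  a regular grid and are deleted afterwards.  An in-band sinusoid with 5
  censored frames is reconstructed to < 0.1% error.
- **Band-pass**: order-4 Butterworth 0.009–0.08 Hz applied forward-backward
  (zero phase).  Measured gains: ≈ 1.00 at 0.03 Hz, < 1e-4 at 0.2 Hz.
- **Retention**: after censored frames are deleted, runs keeping < 180 s of
  data (boundary inclusive) are excluded; retained/censored counts are
  always reported so censoring can be compared across conditions.

## Connectivity

ROI time courses are unweighted means over voxels whose centers fall within
6 mm of the seed center (world coordinates via the NIfTI affine, 0-based
voxel indices; membership by center, not partial overlap, keeping sphere
size identical across subjects).  Edges are Pearson r over retained frames,
Fisher-z transformed (z = atanh r; |r| = 1 is an error unless clipping at
1 − 1e-7 is enabled).  Ten regions give 45 unique edges; the network summary
is the arithmetic mean of the unique-edge z values (z-averaging, matching
the transform-before-statistics convention), ΔFC = z(S2) − z(S1)
elementwise, and group summaries always average within subject before
across subjects.  DVAN and DMN matrices carry their set label and cross-set
operations raise.  The DMN seed coordinates are synthetic placeholders (the
source design names the regions without printing coordinates); override
them from TSV for real analyses.

## Statistics

- **Mixed repeated-measures ANOVA**: standard univariate split-plot
  decomposition; between effect tested against subjects-within-groups,
  within and interaction against the subject × within residual; effect size
  partial η² = SS_effect/(SS_effect + SS_error).  Verified against pingouin
  to 1e-9 on SS, F and df.
- **Sphericity**: Mauchly's W on the pooled within-group covariance (error
  df N − k groups, the SPSS convention); the χ² approximation is the
  standard first-order one (df k(k−1)/2 − 1).  Greenhouse–Geisser ε from
  the eigenvalues of the contrast-projected covariance, bounded in
  [1/(k−1), 1]; with > 2 within levels and Mauchly p < .05 (or always, on
  request) ε multiplies the within/interaction df.  Note the correction is
  guaranteed conservative only when F ≥ 1; for F < 1 shrinking both df can
  lower the tail probability.
- **Homogeneity**: Levene's test (mean center; median center = the
  Brown-Forsythe variance test).  When it rejects (or on request) the
  one-way ANOVA reports the Brown-Forsythe F* for means,
  F* = SS_between / Σ(1 − n_i/N)s_i², with Satterthwaite denominator df;
  F* reduces to the classical F under equal variances and equal n.
- **t-tests**: two-sided throughout; paired d = mean(diff)/sd(diff),
  independent d on the pooled sd, Welch–Satterthwaite df on request;
  Bonferroni multiplies p by the number of comparisons (capped at 1).
- **Regression**: simple OLS with intercept; R² equals the squared Pearson
  correlation by construction, p is the slope's t-test.
- **Multiplicity**: Benjamini–Hochberg step-up (mask and adjusted p);
  BH discoveries are a superset of Bonferroni discoveries at the same level.
- **Edge-level analyses** treat each subject × edge as an observation, as in
  the replicated design; the output metadata flags that the 45 edges of a
  subject are not independent (they share 10 underlying time courses), so
  edge-level p-values are anti-conservative and should be read as
  descriptive.  On synthetic nulls the network-level interaction test is
  calibrated (5.03% rejections over 6000 replicates) while the edge-level
  one is not — exactly the caveat the flag records.

## FIR GLM

One indicator column per (condition, lag) over a 20 s window at TR = 2 s
(10 lags per condition) plus intercept and linear drift; OLS betas with
per-unit residual variance.  The peak contrast averages the four lag betas
bracketing the 4 s response peak — lags 1–4, the 2–8 s window ("four volumes
surrounding the peak" is ambiguous between {0..3} and {1..4}; the later
window is the default and configurable) — with a per-unit t statistic and
BH thresholding at q = 0.05.

## Numerical and design choices

- Seeds: every generator takes a seed or `numpy.random.Generator`; the
  pipeline derives per-stage streams from one root seed, and a saved YAML
  config reproduces byte-identical outputs.
- Degenerate inputs: zero-variance ROIs, non-PSD correlation targets (the
  offending eigenvalue is named), rank-deficient designs, too-short runs and
  out-of-order pipeline stages all raise with actionable messages.
- The two tasks' observers are simulated independently (no shared attention
  resource); staircases for the two tasks run sequentially.
- Nuisance regression precedes detrending; the order is fixed and recorded.

## Limitations

- The synthetic BOLD model has no hemodynamic forward model; FIR recovery
  tests use impulse-train designs with known lag profiles instead.
- Recovery and calibration results quantify estimator behavior under the
  stated generative world; they do not certify performance on real data with
  registration errors, physiological noise, or non-stationary motion.
- Printed fractional degrees of freedom from the original edge-level
  Brown-Forsythe analyses depend on the original subject-level variances and
  are not reproducible without the deposited data; the formulas are
  implemented and tested on synthetic fixtures.
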