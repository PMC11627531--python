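# Methods

This note documents the models, generators, and numerical choices behind
`gazepipe`, in the spirit of a statistical methods appendix: what is
assumed, what the defaults mean, and what passing tests do and do not show.

## The latent-behavior model

Each trial's ground truth is a piecewise-constant timeline of ROI
fixations. The eye starts on the screen center and switches to the target
ROI at a saccade latency drawn from a Gaussian truncated at 80 ms (a
physiological floor that prevents degenerate timelines), with mean

    latency = base + u_subject + w_item + condition shift,

where `u_subject ~ N(0, subject_sd_ms)` and `w_item ~ N(0, item_sd_ms)`
are random effects on the latency scale. Defaults: base 250 ms, latency SD
60 ms, subject SD 40 ms, item SD 20 ms — typical visual-world saccade
timing magnitudes. Two condition-effect mechanisms are supported:

* **cohort-style**: with probability `competitor_prob` the trial contains a
  competitor-ROI fixation of `competitor_dwell_ms` (default 300 ms) placed
  uniformly inside a configured effect window (default 400–900 ms after
  alignment zero). The cohort/control contrast is a probability excess
  (default 0.15 over a 0.08 baseline), so the excess looking is confined
  to the window by construction.
* **anticipatory-style**: a per-condition latency shift.

`stray_rate_hz` adds brief (150 ms) Poisson-timed refixations to a random
other ROI. It is off by default so noise-free timelines are exactly
center-then-target, but the cohort generator enables it (0.15 Hz): real
trials always contain background looking noise, and without it entire
post-effect windows can be response-constant, which repeatedly triggers
the carry-forward fallback and smears detected clusters to the trial end.
Strays are condition-balanced and do not move condition contrasts.

## Measurement channels

A channel renders a timeline into samples at `fps` (first sample at t = 0,
spacing 1000/fps ms, optional uniform clock jitter): coordinates (ROI
centroid at the lag-shifted time, plus error, clipped to the unit square)
or annotation labels (the lagged ROI, with a label-confusion rate).
Spatial error has two components: per-sample jitter (`spatial_sd`) and a
per-trial calibration offset (`bias_sd`), both per-axis Gaussian. The
trial-level component matters: with purely independent jitter the 30%
binarization is extremely forgiving (a bin's indicator survives even 0.15
jitter), whereas calibration drift — the dominant error mode of webcam
gaze estimators — moves whole trials across ROI boundaries and is what
actually degrades binned look proportions. Whole-trial loss and
per-sample track loss are independent Bernoulli processes. Quadrant
centroids sit at the quadrant centers (0.25/0.75 combinations); the
center ROI at (0.5, 0.5).

The bundled defaults (60 fps precise; 25 fps labels with 2% confusion;
26 fps with 0.10 jitter, 0.08 bias, 250 ms lag, 1.2% trial loss) are
*illustrative* channels with the right orderings, not estimates of any
specific hardware; only the sampling rates are taken from the methods they
emulate.

`simulate_binned_looks` bypasses rendering and draws per-bin binary looks
directly from the logistic model the downstream analyses assume
(crossed subject/item intercepts on the logit scale, a sum-coded condition
effect confined to a bin window). Calibration and power studies use it;
channel-fidelity studies use the full render path.

## Preprocessing conventions

* Bins are half-open `[k·100, (k+1)·100)` ms from the analysis-window
  start; thresholds are inclusive ("at least" 30% / 50%).
* The binarization denominator counts **all recorded samples** in the bin,
  including invalid/off-screen ones, mirroring the annotation path where
  unknown frames dilute ROI proportions; `valid_only=True` switches to
  valid-sample denominators.
* Screen sides follow the ROI partition on both paths: center and
  off-screen samples count toward neither side. (Counting raw x-halves
  instead inflates pre-onset side proportions to ~0.6 through the
  inclusive 50% threshold on even sample counts.)
* Empty bins are missing, not zero, and are excluded from model fitting.
* Trial exclusion is strictly `> 0.5` off-screen fraction and propagates
  from the annotation stream to co-recorded channels; trials absent from a
  channel (server loss) are not removed elsewhere.
* The center square is square in physical units: its x half-extent is
  `center_fraction / 2 / aspect_ratio`, so the display aspect ratio is a
  required geometry input. Quadrant ties at exactly 0.5 go to the
  top/left.

## The per-bin mixed model

The fitter maximizes the Laplace-approximate marginal likelihood of a
Bernoulli-logit model with independent (diagonal) Gaussian random-effect
terms — crossed intercepts, optionally condition slopes. For fixed
variance parameters the joint (β, u) mode is found by damped Newton
iteration; the profile over log-SDs uses Nelder-Mead. Intercept-slope
correlations are not estimated; the "maximal" observed-effect model is
therefore the standard zero-correlation variant, and the simplification
ladder on non-convergence is slopes → subject slope only → intercepts.

Conventions: sum-coded two-level factors are ±1 (first sorted level +1),
so a condition coefficient is half the condition difference on the logit
scale — this rescales β but not z. "Singular" means any SD below 1e-3
(variance 1e-6); singular fits are converged. Non-convergence means
separation/inestimability (|β| > 15, non-finite or huge SEs, or a
response without variation); such bins trigger the carry-forward rule.
Tests pin the fitter to three oracles: ordinary logistic regression at
zero variance (≤ 1e-4 on the logit scale), exact Gauss-Hermite ML for a
single grouping factor, and `lme4::glmer` (agreement ~0.01 on β; the two
Laplace implementations profile β slightly differently).

## Cluster-mass permutation test

Observed and permuted datasets are scanned by the identical prepared code
path, including the fallback rules: a non-converged bin inherits the
previous bin's (estimate, SE, z); the first bin reports zeros. The null
statistic is the **maximum** cluster z-sum per permutation (0 when none),
the max-statistic convention that controls family-wise error; a pooled
"all cluster z-sums" variant is available behind `null_statistic="all"`.
p is the proportion of null statistics ≥ the observed z-sum (inclusive);
p = 0 prints as "< 0.001". Permutation streams derive from the master
seed by counter, so results are order-independent and reproducible, and an
exhaustive enumeration mode replaces sampling on tiny datasets.

Numerical choice: by default each bin's variance components are estimated
once, from an intercept-only null model whose likelihood the label
shuffles do not touch, and held fixed across the observed and all permuted
scans (β is still refit everywhere). This keeps the statistic a
deterministic function applied symmetrically to observed and permuted
data — exchangeability is preserved — while making each permuted scan a
single penalized solve; z agrees with full per-scan re-profiling to ~0.005
in checks, and `reestimate_variance=True` restores full re-profiling.
Bins whose null model is inestimable borrow the nearest estimable bin's
components. For the target-side scheme the variance source is the observed
response's own fit (there is no sub-model without the focal intercept);
its dependence on the observed sides is the one deviation from strict
label-invariance and is negligible in calibration checks.

## Effect sizes and power

The d conversion is d = 2z/√(n_obs − n_fixed), i.e. the usual
t-to-d conversion with the Wald z standing in for t, because binomial
fits carry no residual degrees of freedom; `dof="n"` switches the
denominator. Multi-bin windows add a time-bin random intercept. When
several disjoint significant clusters exist, cluster-mode values are
computed per cluster, never pooled. For the fixation metric the cluster
window is the overlap of the positive-significant horizontal and vertical
side clusters.

Power simulation draws fresh subject *and* item effects from the fitted
variance components at each simulated dataset (a parametric procedure;
the item-set size and per-subject trial counts of the original design are
preserved), simulates responses from the fitted fixed effects, and refits
the structure the observed model converged with, warm-started at the
generating parameters — the same deterministic settings for every
dataset. Refit failures are counted and excluded from the power
denominator, never silently dropped. Null calibration (β forced to 0)
reproduces the nominal 0.05 size of the |z| > 2 test.

## Pursuit analysis

The stimulus trajectory generator (constant speed between uniform random
waypoints in the bounding rectangle, 0.25 screen proportions/s by
default) is a synthetic stand-in for an unspecified randomized routine;
only its qualitative character is emulated. A bin's stimulus position is
the track at the bin midpoint (midpoint minimizes within-bin bias). The
t-tests operate on per-bin subject-aggregated mean offsets — one value
per time bin per dataset — paired across bins within a session and Welch
two-sample across samples.

## Problem sizes and what the tests show

The validation suite runs the statistical checks at desk scale: 100 null
datasets × 100 permutations for family-wise error, 50 simulated
experiments at n = 20 subjects for effect recovery, 100 runs per metric
for the effect-size ordering, 500 simulations per sample size for the
power null calibration. These sizes give Monte-Carlo standard errors well
inside the asserted bands. The generator reproduces the statistical
structure the analyses assume — binary binned looks with crossed random
variation, windowed effects, channel noise — but not everything about real
recordings: no smooth saccade trajectories, no pupil or blink dynamics, no
drift correction, no coder disagreement structure beyond uniform label
confusion. Passing tests therefore validate the *inference machinery* and
its calibration, not any claim about a particular eye-tracker's empirical
accuracy; the bundled channel parameters are illustrative by design.
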