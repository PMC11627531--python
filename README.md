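# gazepipe

Simulation and time-course inference for multi-method visual-world
eye-tracking data.

Language researchers increasingly record gaze with whatever camera is at
hand: a research-grade infrared tracker, a human coder stepping through
webcam video frame by frame, or a browser-based gaze estimator. These
channels differ enormously in sampling rate, spatial error, and lag, and
the question for anyone designing a web-based visual-world study is whether
the statistical effects they care about — target fixations, phonemic cohort
competition, verb-mediated anticipatory looks — survive each channel's
noise, and at what sample size. `gazepipe` implements the full analysis
stack used to answer that question, together with a synthetic multi-method
gaze generator so every stage can be validated against known ground truth.

## What it computes

**Preprocessing.** Screen positions are normalized to screen proportions
((0,0) top-left, (1,1) bottom-right). Each sample is assigned to exactly
one region of interest: a central square whose side is 15% of screen
height, or one of the four quadrants minus that overlap. Looks are analyzed
in 100 ms bins: an ROI indicator is 1 when at least 30% of the bin's
recorded samples fall in the ROI (screen *sides* use a 50% threshold), and
trials with more than 50% off-screen/unknown annotation frames are excluded
as inattentive.

**Cluster-mass permutation inference.** For each bin a binomial-logit mixed
model with crossed subject and item random intercepts is fit and the Wald
*z* of a focal term extracted — the intercept against 50% chance for
fixation-style analyses, a sum-coded (±1) condition effect for
cohort-style analyses. Bins with |*z*| > 2 are merged into same-sign runs
scored by the **z-sum** (Σ|z|); the null distribution of the maximum
cluster z-sum is built by re-scanning datasets whose labels are shuffled
within the appropriate exchangeability scheme (condition within subject,
method within subject, experiment between subjects, or per-trial target-side
redraws with the side-look response re-derived). Non-converged bins inherit
the previous bin's estimates (zeros at the first bin), identically in
observed and permuted scans. Clusters with *p* < 0.05 are significant.

**Effect sizes.** Three windows bracket the true effect: the full analysis
window (an underestimate), the significant cluster's window, and the single
peak bin (an overestimate). The metric is a grand-average look proportion
(fixation tasks) or a Cohen's *d* from a window-level mixed model,
converted as *d* = 2*z*/√(n − p).

**Smooth pursuit.** Per-bin mean gaze is compared with a moving stimulus by
the Euclidean offset √((x_t−x_g)² + (y_t−y_g)²) in screen proportion,
aggregated over subjects, and compared between channels by paired or Welch
t-tests on the per-bin means.

**Power.** The observed effect is defined on the 3 bins around the peak
per-bin *d*; trials are collapsed to the proportion of window bins with
competitor looks, binarized at 30%, and fit with a sum-coded condition
effect and maximal (uncorrelated) random effects. Power at n = 20…60
subjects is the fraction of simulated-and-refit datasets with focal
|*z*| > 2.

The per-bin fitter is an in-package maximum-likelihood/Laplace
implementation for crossed random intercepts and slopes; tests verify it
against ordinary logistic regression (variances at zero), an exact
Gauss-Hermite oracle, and `lme4::glmer`.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (16 subjects, three channels). After `python analysis/01_simulate_datasets.py`
and `02_preprocess_bin.py`, the cluster inference step prints:

```
== phonemic cohort: condition effect on competitor looks ==
  infrared: cohort effect 400-999 ms, z-sum = 24.57, p < 0.001
  manual: cohort effect 400-899 ms, z-sum = 20.53, p < 0.001
  webgazer: cohort effect 800-1099 ms, z-sum = 10.25, p < 0.001
```

The injected competitor-look effect lives in 400–900 ms: the precise
channels recover it in place, while the noisy lagged estimator channel
finds it late and attenuated. The effect-size step prints the three-window
bracket per channel (analysis ≤ cluster ≤ maximum):

```
           task  channel     metric  analysis  cluster  maximum
phonemic_cohort infrared   cohens_d     0.187    0.325    0.427
phonemic_cohort   manual   cohens_d     0.181    0.351    0.445
phonemic_cohort webgazer   cohens_d     0.048    0.287    0.305
```

and the pursuit and power steps quantify the channel gap directly:

```
infrared: grand mean offset 2.5% of screen (SD 0.3%)
webgazer: grand mean offset 11.4% of screen (SD 1.6%)
paired t-test (per-bin means): t(449) = -117.47, p = 0

infrared: peak window [500, 799] ms, beta = 0.680 (z = 4.51)
  power: n=20: 100%  n=30: 100%  n=40: 100%  n=50: 100%  n=60: 100%
webgazer: peak window [700, 999] ms, beta = 0.169 (z = 1.88)
  power: n=20: 50%  n=30: 67%  n=40: 83%  n=50: 86%  n=60: 92%
```

— the noisy channel needs roughly twice the participants for comparable
power, the practical message of the method comparison.

A `gazepipe` command-line interface exposes the same stages
(`simulate`, `preprocess`, `cluster`, `effectsize`, `pursuit`, `power`,
`run`); see `gazepipe --help`.

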