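"""Synthetic multi-method gaze data with known ground truth.

The generator separates *latent looking behavior* from *measurement
channels*.  For each subject x trial a latent timeline of ROI fixations is
sampled: the eye starts on the screen center, switches to the target ROI at
a saccade latency drawn from a truncated Gaussian (floor 80 ms, a
physiological minimum), and — in cohort-style conditions — may detour
through the competitor ROI inside a configured effect window.  The same
timeline is then rendered through each recording channel, emulating the
within-session design in which all methods observe the identical behavior:
channels differ in sampling rate, per-axis Gaussian spatial error, constant
temporal lag, per-sample track loss, whole-trial loss, and output mode
(screen coordinates for estimator-style channels, frame-by-frame ROI labels
for manual-annotation-style channels).

The bundled channel parameter sets are illustrative: the sampling rates
match the methods they emulate (60 fps infrared, 12/26 fps gaze estimation,
25 fps annotated video), but the noise magnitudes are plausible choices,
not estimates of any particular hardware.

``simulate_binned_looks`` generates per-bin binary look indicators directly
from a logistic model with crossed subject/item random intercepts — the
statistical structure the downstream models assume — for calibration and
power studies where rendering coordinates would add nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import (
    CENTER,
    OFF_OR_UNKNOWN,
    QUADRANTS,
    ROI_CENTROIDS,
)

__all__ = [
    "MethodModel",
    "TaskDesign",
    "ConditionEffect",
    "EffectSpec",
    "LatentTimeline",
    "default_methods",
    "task_design",
    "sample_timeline",
    "render_coordinates",
    "render_labels",
    "simulate_experiment",
    "simulate_binned_looks",
    "SimResult",
]

_MIN_LATENCY_MS = 80.0
_VISIBLE_ROIS = (CENTER,) + QUADRANTS


@dataclass(frozen=True)
class MethodModel:
    """Generative parameters of one simulated eye-tracking channel."""

    name: str
    fps: float
    spatial_sd: float = 0.0  # per-axis Gaussian error, screen-proportion units
    latency_ms: float = 0.0
    trackloss_rate: float = 0.0
    trial_loss_rate: float = 0.0
    output_mode: str = "coordinates"  # or "labels"
    label_error_rate: float = 0.0
    jitter_ms: float = 0.0  # optional sample-clock jitter (uniform +/- jitter)
    bias_sd: float = 0.0  # per-trial, per-axis calibration-offset SD

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.spatial_sd < 0 or self.bias_sd < 0:
            raise ValueError("spatial_sd and bias_sd must be >= 0")
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be >= 0")
        for r in (self.trackloss_rate, self.trial_loss_rate, self.label_error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.output_mode not in ("coordinates", "labels"):
            raise ValueError("output_mode must be 'coordinates' or 'labels'")


def default_methods() -> dict[str, MethodModel]:
    """Three illustrative channels: precise/fast, annotated video, noisy estimator."""
    return {
        "infrared": MethodModel("infrared", fps=60, spatial_sd=0.03, trackloss_rate=0.02),
        "manual": MethodModel(
            "manual", fps=25, output_mode="labels", label_error_rate=0.02, trackloss_rate=0.03
        ),
        "webgazer": MethodModel(
            "webgazer",
            fps=26,
            spatial_sd=0.10,
            bias_sd=0.08,
            latency_ms=250,
            trackloss_rate=0.05,
            trial_loss_rate=0.012,
        ),
    }


@dataclass(frozen=True)
class TaskDesign:
    """Trial structure of one task, in trial-clock milliseconds."""

    task: str
    trial_count: int
    trial_duration_ms: int
    align_zero_ms: int  # target/word onset within the trial
    center_fraction: float = 0.15
    aspect_ratio: float = 16 / 9
    condition_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0 < self.align_zero_ms < self.trial_duration_ms:
            raise ValueError("align_zero_ms must lie inside the trial")
        if self.trial_count <= 0:
            raise ValueError("trial_count must be positive")


_TASKS = {
    # fixation: 750 ms center fixation then target circle on screen for 1500 ms
    "fixation": dict(trial_count=32, trial_duration_ms=2250, align_zero_ms=750),
    # lexical fixation: 16 trials, cue word at alignment zero
    "lexical_fixation": dict(trial_count=16, trial_duration_ms=3100, align_zero_ms=1600),
    # phonemic cohort: 36 trials, half cohort / half control
    "phonemic_cohort": dict(
        trial_count=36,
        trial_duration_ms=3100,
        align_zero_ms=1600,
        condition_labels=("cohort", "control"),
    ),
    # anticipatory looking: 16 trials, window extends 700 ms before target onset
    "anticipatory": dict(
        trial_count=16,
        trial_duration_ms=2700,
        align_zero_ms=1700,
        condition_labels=("constraining", "non_constraining"),
    ),
    # smooth pursuit: single 45 s tracking trial after a 750 ms fixation
    "pursuit": dict(trial_count=1, trial_duration_ms=45750, align_zero_ms=750),
}


def task_design(task: str, **overrides) -> TaskDesign:
    if task not in _TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(_TASKS)}")
    kw = dict(_TASKS[task])
    kw.update(overrides)
    return TaskDesign(task=task, **kw)


@dataclass(frozen=True)
class ConditionEffect:
    """Per-condition parameters of the latent behavior.

    ``latency_shift_ms`` shifts the saccade latency (anticipatory-style
    effects use a negative shift in the constraining condition).
    ``competitor_prob`` is the probability that the trial contains a
    competitor-ROI fixation of ``competitor_dwell_ms`` placed uniformly
    inside ``competitor_window`` (ms relative to alignment zero).
    """

    latency_shift_ms: float = 0.0
    competitor_prob: float = 0.0
    competitor_window: tuple[float, float] = (400.0, 900.0)
    competitor_dwell_ms: float = 300.0

    def __post_init__(self):
        if not 0 <= self.competitor_prob <= 1:
            raise ValueError("competitor_prob must lie in [0, 1]")
        if self.competitor_window[1] <= self.competitor_window[0]:
            raise ValueError("competitor window must be a nonempty interval")
        if self.competitor_dwell_ms <= 0:
            raise ValueError("competitor_dwell_ms must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Latent-behavior parameters: latency distribution and condition effects.

    ``stray_rate_hz`` adds brief task-unrelated refixations (to a uniformly
    random other visible ROI) at the given Poisson rate — the background
    looking noise real trials always contain.  It is 0 by default so that
    noise-free timelines are exactly center-then-target; condition-balanced,
    it leaves condition contrasts untouched.
    """

    base_latency_ms: float = 250.0
    latency_sd_ms: float = 60.0
    subject_sd_ms: float = 40.0
    item_sd_ms: float = 20.0
    condition_effects: dict = field(default_factory=dict)
    stray_rate_hz: float = 0.0
    stray_dwell_ms: float = 150.0

    def __post_init__(self):
        for sd in (self.latency_sd_ms, self.subject_sd_ms, self.item_sd_ms):
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        if self.stray_rate_hz < 0 or self.stray_dwell_ms <= 0:
            raise ValueError("stray parameters must be nonnegative (dwell positive)")

    def effect(self, condition: str | None) -> ConditionEffect:
        if condition is None:
            return ConditionEffect()
        return self.condition_effects.get(condition, ConditionEffect())


def cohort_effects(
    excess: float = 0.15,
    base_prob: float = 0.08,
    window: tuple[float, float] = (400.0, 900.0),
    dwell_ms: float = 300.0,
    stray_rate_hz: float = 0.15,
    **kwargs,
) -> EffectSpec:
    """Cohort-style spec: competitor-look probability raised by ``excess`` in
    the cohort condition, confined to ``window``."""
    return EffectSpec(
        stray_rate_hz=stray_rate_hz,
        condition_effects={
            "cohort": ConditionEffect(
                competitor_prob=base_prob + excess,
                competitor_window=window,
                competitor_dwell_ms=dwell_ms,
            ),
            "control": ConditionEffect(
                competitor_prob=base_prob,
                competitor_window=window,
                competitor_dwell_ms=dwell_ms,
            ),
        },
        **kwargs,
    )


@dataclass
class LatentTimeline:
    """Ground-truth fixation sequence for one trial (trial clock, ms)."""

    intervals: list[tuple[float, float, str]]
    duration_ms: float
    align_zero_ms: float
    condition: str | None = None
    effect_window: tuple[float, float] | None = None  # relative to alignment zero
    latency_ms: float | None = None  # saccade latency relative to alignment zero

    def __post_init__(self):
        t = 0.0
        for s, e, _roi in self.intervals:
            if not np.isclose(s, t) or e <= s:
                raise ValueError("intervals must partition [0, duration)")
            t = e
        if not np.isclose(t, self.duration_ms):
            raise ValueError("intervals must cover the full trial")

    def roi_at(self, times_ms) -> np.ndarray:
        """ROI active at each trial-clock time (vectorized)."""
        times = np.atleast_1d(np.asarray(times_ms, float))
        edges = np.array([s for s, _, _ in self.intervals] + [self.duration_ms])
        labels = np.array([r for _, _, r in self.intervals], dtype=object)
        idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(labels) - 1)
        return labels[idx]


def _truncated_latency(loc: float, scale: float, rng: np.random.Generator) -> float:
    if scale == 0:
        return max(loc, _MIN_LATENCY_MS)
    a = (_MIN_LATENCY_MS - loc) / scale
    return float(stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale, random_state=rng))


def sample_timeline(
    design: TaskDesign,
    effects: EffectSpec,
    subject_re: float,
    item_re: float,
    condition: str | None,
    rng: np.random.Generator,
    target_roi: str = "top_left",
    competitor_roi: str | None = None,
) -> LatentTimeline:
    """Sample one trial's latent fixation timeline.

    The eye rests on the center ROI, switches to ``target_roi`` at
    latency = base + subject_re + item_re + condition shift (truncated
    Gaussian, >= 80 ms, measured from alignment zero), and in cohort-style
    conditions may insert a competitor fixation inside the effect window.
    """
    if condition is not None and design.condition_labels and condition not in design.condition_labels:
        raise ValueError(f"condition {condition!r} not in design conditions {design.condition_labels}")
    eff = effects.effect(condition)
    post = design.trial_duration_ms - design.align_zero_ms
    loc = effects.base_latency_ms + subject_re + item_re + eff.latency_shift_ms
    latency = _truncated_latency(loc, effects.latency_sd_ms, rng)
    t_switch = min(design.align_zero_ms + latency, design.trial_duration_ms)

    comp: tuple[float, float] | None = None
    if eff.competitor_prob > 0:
        ws, we = eff.competitor_window
        if ws < -design.align_zero_ms or we > post:
            raise ValueError(
                f"effect window {eff.competitor_window} lies outside the trial "
                f"(valid range {-design.align_zero_ms}..{post} ms from alignment zero)"
            )
        if rng.random() < eff.competitor_prob:
            dwell = min(eff.competitor_dwell_ms, we - ws)
            c0 = design.align_zero_ms + ws + rng.uniform(0.0, (we - ws) - dwell)
            comp = (c0, c0 + dwell)

    # brief task-unrelated refixations at a Poisson rate (background noise)
    strays: list[tuple[float, float, str]] = []
    if effects.stray_rate_hz > 0:
        t = rng.exponential(1000.0 / effects.stray_rate_hz)
        while t < design.trial_duration_ms:
            base = target_roi if t >= t_switch else CENTER
            others = [r for r in _VISIBLE_ROIS if r != base]
            roi = others[rng.integers(len(others))]
            strays.append((t, min(t + effects.stray_dwell_ms, design.trial_duration_ms), roi))
            t += effects.stray_dwell_ms + rng.exponential(1000.0 / effects.stray_rate_hz)

    # base sequence center -> target, stray fixations overlaid, the
    # condition-carrying competitor interval overlaid last
    breaks = {0.0, design.trial_duration_ms, t_switch}
    for s, e, _r in strays:
        breaks.update((s, e))
    if comp:
        breaks.update(comp)
    edges = sorted(b for b in breaks if 0.0 <= b <= design.trial_duration_ms)
    intervals = []
    for s, e in zip(edges[:-1], edges[1:]):
        if e <= s:
            continue
        mid = 0.5 * (s + e)
        if comp and comp[0] <= mid < comp[1] and competitor_roi is not None:
            roi = competitor_roi
        else:
            roi = target_roi if mid >= t_switch else CENTER
            for s0, e0, r0 in strays:
                if s0 <= mid < e0:
                    roi = r0
        intervals.append((s, e, roi))
    # merge adjacent intervals with the same ROI
    merged = [list(intervals[0])]
    for s, e, r in intervals[1:]:
        if r == merged[-1][2]:
            merged[-1][1] = e
        else:
            merged.append([s, e, r])
    return LatentTimeline(
        intervals=[tuple(iv) for iv in merged],
        duration_ms=float(design.trial_duration_ms),
        align_zero_ms=float(design.align_zero_ms),
        condition=condition,
        effect_window=tuple(eff.competitor_window) if eff.competitor_prob > 0 else None,
        latency_ms=latency,
    )


def _sample_times(duration_ms: float, method: MethodModel, rng: np.random.Generator) -> np.ndarray:
    step = 1000.0 / method.fps
    t = np.arange(0.0, duration_ms, step)
    if method.jitter_ms > 0:
        t = np.clip(t + rng.uniform(-method.jitter_ms, method.jitter_ms, t.shape), 0, duration_ms - 1e-9)
        t.sort()
    return t


def render_coordinates(
    timeline: LatentTimeline, method: MethodModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Render a timeline as a coordinate stream through one channel.

    Sample k is taken at t = k/fps; its position is the centroid of the ROI
    active at (t - latency), plus a per-trial calibration offset
    (Gaussian with SD ``bias_sd``, shared by all the trial's samples) and
    per-sample Gaussian jitter with SD ``spatial_sd``, clipped to the
    screen; track-lost samples are invalid with NaN coordinates.
    """
    if method.output_mode != "coordinates":
        raise ValueError("method does not output coordinates")
    t = _sample_times(timeline.duration_ms, method, rng)
    lagged = np.clip(t - method.latency_ms, 0.0, timeline.duration_ms - 1e-9)
    roi = timeline.roi_at(lagged)
    xy = np.array([ROI_CENTROIDS.get(r, (np.nan, np.nan)) for r in roi])
    if method.bias_sd > 0:
        xy = xy + rng.normal(0.0, method.bias_sd, (1, 2))
    if method.spatial_sd > 0:
        xy = xy + rng.normal(0.0, method.spatial_sd, xy.shape)
    xy = np.clip(xy, 0.0, 1.0)
    valid = np.isfinite(xy[:, 0])
    if method.trackloss_rate > 0:
        valid &= rng.random(len(t)) >= method.trackloss_rate
    xy[~valid] = np.nan
    return pd.DataFrame({"time_ms": t, "x": xy[:, 0], "y": xy[:, 1], "valid": valid})


def render_labels(
    timeline: LatentTimeline, method: MethodModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Render a timeline as an annotation-frame stream through one channel."""
    if method.output_mode != "labels":
        raise ValueError("method does not output labels")
    t = _sample_times(timeline.duration_ms, method, rng)
    lagged = np.clip(t - method.latency_ms, 0.0, timeline.duration_ms - 1e-9)
    labels = timeline.roi_at(lagged).copy()
    if method.label_error_rate > 0:
        err = rng.random(len(t)) < method.label_error_rate
        for i in np.nonzero(err)[0]:
            others = [r for r in _VISIBLE_ROIS if r != labels[i]]
            labels[i] = others[rng.integers(len(others))]
    if method.trackloss_rate > 0:
        lost = rng.random(len(t)) < method.trackloss_rate
        labels[lost] = OFF_OR_UNKNOWN
    return pd.DataFrame({"time_ms": t, "label": labels.astype(str)})


@dataclass
class SimResult:
    """One simulated experiment: per-method sample tables plus ground truth."""

    datasets: dict[str, pd.DataFrame]
    design_table: pd.DataFrame
    truth: dict
    design: TaskDesign
    effects: EffectSpec
    seed: int


def _target_sides(target_roi: str) -> tuple[str, str]:
    h = "left" if target_roi in ("top_left", "bottom_left") else "right"
    v = "top" if target_roi in ("top_left", "top_right") else "bottom"
    return h, v


def simulate_experiment(
    n_subjects: int,
    n_items: int,
    design: TaskDesign,
    effects: EffectSpec,
    methods: dict[str, MethodModel] | list[MethodModel],
    seed: int,
) -> SimResult:
    """Simulate one multi-method experiment with shared latent behavior.

    One latent timeline is sampled per subject x trial and rendered once
    through *each* channel (the within-session recording design); whole
    trials are dropped independently per method at its trial-loss rate.
    Output times are relative to the trial's alignment zero.  Fully
    reproducible from ``seed``; ground truth is returned alongside.
    """
    if n_subjects < 1 or n_items < 1:
        raise ValueError("need at least one subject and one item")
    if isinstance(methods, dict):
        methods = list(methods.values())
    if not methods:
        raise ValueError("empty method list")

    conditions = design.condition_labels or ("all",)
    rng_master = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    subject_re = rng_master.normal(0.0, effects.subject_sd_ms, n_subjects)
    item_re = rng_master.normal(0.0, effects.item_sd_ms, n_items)

    rows_design = []
    timelines: dict[tuple[int, int], LatentTimeline] = {}
    quads = list(QUADRANTS)
    for s in range(n_subjects):
        rng_s = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, s)))
        # balanced condition assignment, randomized order per subject
        conds = np.tile(conditions, int(np.ceil(design.trial_count / len(conditions))))
        conds = conds[: design.trial_count]
        conds = conds[rng_s.permutation(design.trial_count)]
        for t_idx in range(design.trial_count):
            item = t_idx % n_items
            target = quads[(t_idx + s) % 4]
            competitor = quads[(t_idx + s + 2) % 4]  # diagonal quadrant
            tl = sample_timeline(
                design,
                effects,
                float(subject_re[s]),
                float(item_re[item]),
                conds[t_idx],
                rng_s,
                target_roi=target,
                competitor_roi=competitor,
            )
            timelines[(s, t_idx)] = tl
            side_h, side_v = _target_sides(target)
            rows_design.append(
                dict(
                    subject=s,
                    trial=t_idx,
                    item=item,
                    condition=conds[t_idx],
                    target_roi=target,
                    competitor_roi=competitor,
                    target_side_h=side_h,
                    target_side_v=side_v,
                    latency_ms=tl.latency_ms,
                )
            )
    design_table = pd.DataFrame(rows_design)

    datasets: dict[str, pd.DataFrame] = {}
    lost: dict[str, list] = {}
    for m_idx, method in enumerate(methods):
        frames = []
        lost[method.name] = []
        for s in range(n_subjects):
            for t_idx in range(design.trial_count):
                rng_c = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(2, m_idx, s, t_idx))
                )
                if method.trial_loss_rate > 0 and rng_c.random() < method.trial_loss_rate:
                    lost[method.name].append((s, t_idx))
                    continue
                tl = timelines[(s, t_idx)]
                if method.output_mode == "coordinates":
                    f = render_coordinates(tl, method, rng_c)
                else:
                    f = render_labels(tl, method, rng_c)
                f["time_ms"] = f["time_ms"] - design.align_zero_ms
                f.insert(0, "subject", s)
                f.insert(1, "trial", t_idx)
                frames.append(f)
        ds = pd.concat(frames, ignore_index=True)
        ds = ds.merge(
            design_table[["subject", "trial", "item", "condition"]], on=["subject", "trial"]
        )
        ds["method"] = method.name
        datasets[method.name] = ds

    truth = {
        "subject_re_ms": subject_re.tolist(),
        "item_re_ms": item_re.tolist(),
        "latency_ms": {f"{s}:{t}": timelines[(s, t)].latency_ms for s, t in timelines},
        "competitor_windows": {
            f"{s}:{t}": timelines[(s, t)].effect_window for s, t in timelines
        },
        "lost_trials": {k: v for k, v in lost.items()},
    }
    return SimResult(datasets, design_table, truth, design, effects, seed)


def simulate_binned_looks(
    n_subjects: int,
    n_items: int,
    n_bins: int,
    effect_window_bins: tuple[int, int] = (0, 0),
    effect_logit: float = 0.0,
    baseline_logit: float = -1.0,
    subject_sd: float = 0.5,
    item_sd: float = 0.3,
    conditions: tuple[str, str] = ("cohort", "control"),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-bin binary looks directly from the downstream model.

    Each subject sees each item once per condition.  The look probability is
    logistic(baseline + c * effect + u_subject + w_item), where the
    condition effect (sum-coded c = +/-1, first condition +1) applies only
    to bins in ``effect_window_bins`` (half-open).  Returns a long table
    (subject, item, trial, condition, bin, look).
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, subject_sd, n_subjects)
    w = rng.normal(0.0, item_sd, n_items)
    subj = np.repeat(np.arange(n_subjects), n_items * 2)
    item = np.tile(np.repeat(np.arange(n_items), 2), n_subjects)
    cvals = np.tile(np.array([1.0, -1.0]), n_subjects * n_items)
    trial = np.tile(np.arange(n_items * 2), n_subjects)
    n_trials = len(subj)
    bins = np.arange(n_bins)
    in_window = (bins >= effect_window_bins[0]) & (bins < effect_window_bins[1])
    eta = baseline_logit + u[subj] + w[item]
    eta_bins = eta[:, None] + np.where(in_window[None, :], cvals[:, None] * effect_logit, 0.0)
    looks = (rng.random((n_trials, n_bins)) < expit(eta_bins)).astype(float)
    out = pd.DataFrame(
        {
            "subject": np.repeat(subj, n_bins),
            "item": np.repeat(item, n_bins),
            "trial": np.repeat(trial, n_bins),
            "condition": np.repeat(np.where(cvals > 0, conditions[0], conditions[1]), n_bins),
            "bin": np.tile(bins, n_trials),
            "look": looks.ravel(),
        }
    )
    return out
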