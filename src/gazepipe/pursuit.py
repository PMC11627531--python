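"""Smooth-pursuit spatial accuracy: gaze-to-stimulus Euclidean offset.

A moving stimulus follows a known trajectory inside a rectangle for 45 s.
Gaze coordinates (screen proportion) are averaged within 100 ms bins, and
each bin's accuracy is the Euclidean distance between the mean gaze
position and the stimulus center,

    offset = sqrt((x_target - x_gaze)^2 + (y_target - y_gaze)^2),

in screen-proportion units.  Per-bin offsets are averaged over subjects to
give one series per dataset; datasets are compared with a paired t-test
(same subjects, e.g. two methods in one session) or a Welch two-sample
t-test (different samples), operating on the per-bin aggregated means so
both series contribute one value per time bin.

The stimulus trajectory generator (constant speed between uniform random
waypoints) is a synthetic stand-in: the original trajectory was produced by
an unspecified randomized routine, so only its qualitative character —
smooth motion confined to a box — is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StimulusTrack",
    "make_trajectory",
    "bin_mean_coordinates",
    "euclidean_offset",
    "subject_offset_series",
    "aggregate_offsets",
    "compare_offset_series",
    "simulate_pursuit_gaze",
]


@dataclass
class StimulusTrack:
    """Sampled stimulus-center positions (trial clock, ms) inside a rectangle."""

    times_ms: np.ndarray
    xy: np.ndarray  # (n, 2) screen proportion
    rect: tuple[float, float, float, float]  # x0, y0, x1, y1

    def position(self, times_ms) -> np.ndarray:
        t = np.atleast_1d(np.asarray(times_ms, float))
        x = np.interp(t, self.times_ms, self.xy[:, 0])
        y = np.interp(t, self.times_ms, self.xy[:, 1])
        return np.column_stack([x, y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times_ms, "x": self.xy[:, 0], "y": self.xy[:, 1]})


def make_trajectory(
    rect: tuple[float, float, float, float] = (0.2, 0.2, 0.8, 0.8),
    speed: float = 0.25,
    duration_ms: float = 45_000.0,
    seed: int = 0,
    step_ms: float = 10.0,
) -> StimulusTrack:
    """Constant-speed piecewise-linear path between uniform random waypoints.

    ``speed`` is in screen proportions per second.  Deterministic given
    ``seed``.  A zero speed yields a stationary track at the first waypoint.
    """
    x0, y0, x1, y1 = rect
    if not (0 <= x0 < x1 <= 1 and 0 <= y0 < y1 <= 1):
        raise ValueError("rect must be a nonempty box inside the unit square")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_ms + step_ms, step_ms)
    start = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
    if speed <= 0:
        xy = np.tile(start, (len(times), 1))
        return StimulusTrack(times, xy, rect)
    # build waypoints until the cumulative path outlasts the trial
    pts = [start]
    total = 0.0
    needed = speed * duration_ms / 1000.0
    while total < needed:
        nxt = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        total += float(np.linalg.norm(nxt - pts[-1]))
        pts.append(nxt)
    pts = np.array(pts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum_t = np.concatenate([[0.0], np.cumsum(seg) / speed * 1000.0])
    x = np.interp(times, cum_t, pts[:, 0])
    y = np.interp(times, cum_t, pts[:, 1])
    return StimulusTrack(times, np.column_stack([x, y]), rect)


def bin_mean_coordinates(samples: pd.DataFrame, bin_ms: int = 100, t_max_ms: float | None = None) -> pd.DataFrame:
    """Average recorded coordinates per 100 ms bin; empty bins are missing."""
    d = samples
    if "valid" in d.columns:
        d = d.loc[d["valid"].astype(bool)]
    d = d.loc[np.isfinite(d["x"]) & np.isfinite(d["y"])].copy()
    d = d.loc[d["time_ms"] >= 0]
    if t_max_ms is not None:
        d = d.loc[d["time_ms"] < t_max_ms]
    d["bin"] = (d["time_ms"] // bin_ms).astype(int)
    out = d.groupby("bin", sort=True)[["x", "y"]].mean().reset_index()
    return out


def euclidean_offset(gaze, target) -> np.ndarray | float:
    """Euclidean distance in screen proportion between gaze and stimulus."""
    g = np.asarray(gaze, float)
    t = np.asarray(target, float)
    d = np.sqrt(np.sum((t - g) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def subject_offset_series(
    gaze: pd.DataFrame, track: StimulusTrack, bin_ms: int = 100, align_zero_ms: float = 0.0
) -> pd.DataFrame:
    """Per subject, per bin: offset between mean gaze and the stimulus.

    ``gaze`` holds rows (subject, time_ms, x, y, valid) with times relative
    to alignment zero; the track runs on the trial clock, so
    ``align_zero_ms`` maps between them.  The stimulus position for a bin is
    the track position at the bin midpoint.
    """
    rows = []
    for s, grp in gaze.groupby("subject", sort=True):
        means = bin_mean_coordinates(grp, bin_ms)
        mids = align_zero_ms + means["bin"].to_numpy() * bin_ms + bin_ms / 2.0
        target = track.position(mids)
        off = euclidean_offset(means[["x", "y"]].to_numpy(), target)
        rows.append(pd.DataFrame({"subject": s, "bin": means["bin"], "offset": off}))
    return pd.concat(rows, ignore_index=True)


def aggregate_offsets(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Mean offset per bin across subjects (one value per time bin)."""
    return per_subject.groupby("bin", sort=True)["offset"].mean().reset_index()


def compare_offset_series(series_a: pd.DataFrame, series_b: pd.DataFrame, paired: bool):
    """Compare two per-bin mean offset series.

    Paired t-test on bin-wise differences when the series come from the same
    subjects; Welch two-sample t-test otherwise.  Returns (t, df, p).
    """
    if paired:
        merged = series_a.merge(series_b, on="bin", suffixes=("_a", "_b")).dropna()
        a = merged["offset_a"].to_numpy()
        b = merged["offset_b"].to_numpy()
        if len(a) < 2:
            raise ValueError("need at least 2 aligned bins")
        d = a - b
        if np.ptp(d) < 1e-12:  # constant difference: t undefined unless it is 0
            if np.abs(d).max() < 1e-12:
                return 0.0, float(len(a) - 1), 1.0
            raise ValueError("zero variance of paired differences with nonzero mean")
        res = stats.ttest_rel(a, b)
        df = len(a) - 1
    else:
        a = series_a["offset"].dropna().to_numpy()
        b = series_b["offset"].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 bins per series")
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("zero variance in both series")
        res = stats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


def simulate_pursuit_gaze(
    track: StimulusTrack,
    n_subjects: int,
    spatial_sd: float,
    fps: float,
    seed: int,
    pursuit_lag_ms: float = 100.0,
    trackloss_rate: float = 0.0,
) -> pd.DataFrame:
    """Synthetic pursuit gaze: each subject tracks the stimulus with a lag
    and per-axis Gaussian error.  Times are on the track's trial clock."""
    frames = []
    dur = float(track.times_ms[-1])
    for s in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(s,)))
        t = np.arange(0.0, dur, 1000.0 / fps)
        pos = track.position(np.clip(t - pursuit_lag_ms, 0, dur))
        pos = np.clip(pos + rng.normal(0.0, spatial_sd, pos.shape), 0.0, 1.0)
        valid = rng.random(len(t)) >= trackloss_rate
        frames.append(
            pd.DataFrame(
                {"subject": s, "time_ms": t, "x": pos[:, 0], "y": pos[:, 1], "valid": valid}
            )
        )
    return pd.concat(frames, ignore_index=True)
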