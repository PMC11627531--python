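"""From raw gaze streams to binned, binarized per-ROI look indicators.

Screen positions are expressed in screen-proportion coordinates: (0, 0) is
the top-left corner, (1, 1) the bottom-right, so the screen center is
(0.5, 0.5) and y increases downward.  A gaze sample is assigned to exactly
one region of interest (ROI): a central square whose side is a fixed
fraction of the screen *height* (15% by default, so its x-extent shrinks by
the display aspect ratio), or one of the four quadrants, defined as the
screen quarters minus any overlap with the center region.  Manual
annotation streams carry these same labels directly, plus an
off-screen/unknown label for blinks, looks away, and unclear frames.

Looks are analyzed in 100 ms bins.  A bin's indicator for an ROI is 1 when
at least 30% of the recorded samples in the bin fall in that ROI; screen
*side* indicators (left/right, top/bottom) use a 50% threshold.  Bins with
no recorded samples are missing, and trials in which more than half of the
annotated frames are off-screen/unknown are excluded as inattentive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CENTER",
    "TOP_LEFT",
    "TOP_RIGHT",
    "BOTTOM_LEFT",
    "BOTTOM_RIGHT",
    "OFF_OR_UNKNOWN",
    "ROI_LABELS",
    "QUADRANTS",
    "ROI_CENTROIDS",
    "RoiGeometry",
    "normalize_coordinates",
    "assign_roi",
    "bin_looks",
    "exclude_trials",
    "apply_exclusions",
    "annotation_agreement",
]

CENTER = "center"
TOP_LEFT = "top_left"
TOP_RIGHT = "top_right"
BOTTOM_LEFT = "bottom_left"
BOTTOM_RIGHT = "bottom_right"
OFF_OR_UNKNOWN = "off_or_unknown"

QUADRANTS = (TOP_LEFT, TOP_RIGHT, BOTTOM_LEFT, BOTTOM_RIGHT)
ROI_LABELS = (CENTER,) + QUADRANTS + (OFF_OR_UNKNOWN,)

# quadrant centroids sit at the quadrant centers; the center ROI at mid-screen
ROI_CENTROIDS = {
    CENTER: (0.5, 0.5),
    TOP_LEFT: (0.25, 0.25),
    TOP_RIGHT: (0.75, 0.25),
    BOTTOM_LEFT: (0.25, 0.75),
    BOTTOM_RIGHT: (0.75, 0.75),
}

_LEFT_QUADS = (TOP_LEFT, BOTTOM_LEFT)
_RIGHT_QUADS = (TOP_RIGHT, BOTTOM_RIGHT)
_TOP_QUADS = (TOP_LEFT, TOP_RIGHT)
_BOTTOM_QUADS = (BOTTOM_LEFT, BOTTOM_RIGHT)

_ID_CANDIDATES = ("subject", "item", "trial", "condition", "method", "experiment")


@dataclass(frozen=True)
class RoiGeometry:
    """Center-square size (as a fraction of screen height) and display aspect.

    The center region is square in physical units, so its half-width in
    x-proportion is ``center_fraction / 2 / aspect_ratio``.
    """

    center_fraction: float = 0.15
    aspect_ratio: float = 16 / 9

    def __post_init__(self):
        if not 0 < self.center_fraction < 1:
            raise ValueError("center_fraction must be in (0, 1)")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect_ratio must be positive")

    @property
    def half_x(self) -> float:
        return 0.5 * self.center_fraction / self.aspect_ratio

    @property
    def half_y(self) -> float:
        return 0.5 * self.center_fraction


def normalize_coordinates(x_px, y_px, screen_width_px: float, screen_height_px: float):
    """Convert pixel coordinates to screen proportions.

    Returns ``(x, y, valid)``; positions outside [0, 1]^2 are flagged invalid
    but returned unchanged.
    """
    if screen_width_px <= 0 or screen_height_px <= 0:
        raise ValueError("screen dimensions must be positive")
    x = np.asarray(x_px, float) / screen_width_px
    y = np.asarray(y_px, float) / screen_height_px
    valid = (x >= 0) & (x <= 1) & (y >= 0) & (y <= 1) & np.isfinite(x) & np.isfinite(y)
    if np.isscalar(x_px):
        return float(x), float(y), bool(valid)
    return x, y, valid


def assign_roi(x, y, valid=None, geom: RoiGeometry = RoiGeometry()):
    """Map each valid coordinate sample to exactly one ROI label.

    The center test is inclusive on its boundary; quadrant membership breaks
    ties toward the left/top (``x <= 0.5`` is left, ``y <= 0.5`` is top).
    Invalid samples map to the off-screen/unknown label.
    """
    scalar = np.isscalar(x)
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    else:
        valid = np.atleast_1d(np.asarray(valid, bool)) & np.isfinite(x) & np.isfinite(y)
    out = np.full(x.shape, OFF_OR_UNKNOWN, dtype=object)
    in_center = (np.abs(x - 0.5) <= geom.half_x) & (np.abs(y - 0.5) <= geom.half_y)
    left = x <= 0.5
    top = y <= 0.5
    out[valid & in_center] = CENTER
    quad = np.where(top, np.where(left, TOP_LEFT, TOP_RIGHT), np.where(left, BOTTOM_LEFT, BOTTOM_RIGHT))
    rest = valid & ~in_center
    out[rest] = quad[rest]
    if scalar:
        return str(out[0])
    return out


def _id_cols(df: pd.DataFrame, id_cols):
    if id_cols is not None:
        return list(id_cols)
    return [c for c in _ID_CANDIDATES if c in df.columns]


def bin_looks(
    df: pd.DataFrame,
    window: tuple[int, int],
    bin_ms: int = 100,
    roi_threshold: float = 0.30,
    side_threshold: float = 0.50,
    geom: RoiGeometry = RoiGeometry(),
    id_cols=None,
    valid_only: bool = False,
) -> pd.DataFrame:
    """Bin and binarize a gaze or annotation stream over an analysis window.

    ``df`` holds one row per sample with ``time_ms`` (relative to the trial's
    alignment zero) plus either coordinates (``x``, ``y``, ``valid``) or an
    annotation ``label``; any of subject/item/trial/condition/method/
    experiment columns present identify the trial.  Bins are half-open
    ``[k*bin_ms, (k+1)*bin_ms)`` from the window start.  Thresholds are
    inclusive ("at least").  The proportion denominator counts all recorded
    samples in the bin, including invalid/off-screen ones; pass
    ``valid_only=True`` to restrict the denominator to valid samples.
    Returns one row per trial x bin, with 0/1 indicators (NaN when the bin
    has no samples) for the five ROIs and the four screen sides.
    """
    start, end = int(window[0]), int(window[1])
    if end <= start or (end - start) % bin_ms:
        raise ValueError("analysis window must be a positive multiple of bin_ms")
    n_bins = (end - start) // bin_ms
    ids = _id_cols(df, id_cols)
    trial_keys = df[ids].drop_duplicates() if ids else pd.DataFrame(index=[0])

    d = df.loc[(df["time_ms"] >= start) & (df["time_ms"] < end)].copy()
    d["bin"] = ((d["time_ms"] - start) // bin_ms).astype(int)

    if "label" in d.columns:
        roi = d["label"].to_numpy()
    else:
        valid = d["valid"].to_numpy(bool) if "valid" in d.columns else np.ones(len(d), bool)
        valid = valid & np.isfinite(d["x"].to_numpy(float)) & np.isfinite(d["y"].to_numpy(float))
        roi = assign_roi(d["x"].to_numpy(float), d["y"].to_numpy(float), valid, geom)
    # sides follow the ROI partition on both paths: center (and off-screen)
    # samples count toward the denominator but toward neither side
    left = np.isin(roi, _LEFT_QUADS)
    right = np.isin(roi, _RIGHT_QUADS)
    top = np.isin(roi, _TOP_QUADS)
    bottom = np.isin(roi, _BOTTOM_QUADS)
    valid = roi != OFF_OR_UNKNOWN

    if valid_only:
        keep = valid
        d, roi = d.loc[keep], roi[keep]
        left, right, top, bottom = left[keep], right[keep], top[keep], bottom[keep]

    for lab in (CENTER,) + QUADRANTS:
        d[lab] = (roi == lab).astype(float)
    d["left"], d["right"], d["top"], d["bottom"] = (
        left.astype(float),
        right.astype(float),
        top.astype(float),
        bottom.astype(float),
    )

    keys = ids + ["bin"]
    agg = d.groupby(keys, sort=True, dropna=False).agg(
        n_samples=("bin", "size"),
        **{c: (c, "mean") for c in (CENTER,) + QUADRANTS + ("left", "right", "top", "bottom")},
    )
    for lab in (CENTER,) + QUADRANTS:
        agg[lab] = (agg[lab] >= roi_threshold).astype(float)
    for lab in ("left", "right", "top", "bottom"):
        agg[lab] = (agg[lab] >= side_threshold).astype(float)

    # reindex to the full trial x bin grid; empty bins become missing
    grid = trial_keys.merge(pd.DataFrame({"bin": np.arange(n_bins)}), how="cross")
    out = grid.set_index(keys).join(agg).reset_index()
    out["n_samples"] = out["n_samples"].fillna(0).astype(int)
    out["missing"] = out["n_samples"] == 0
    return out


def exclude_trials(ann_df: pd.DataFrame, threshold: float = 0.5, id_cols=None) -> pd.DataFrame:
    """Apply the attention-based trial exclusion rule to annotation streams.

    A trial is excluded iff the fraction of off-screen/unknown frames is
    strictly greater than ``threshold`` (default 0.5).  Returns one row per
    trial with ``off_fraction`` and ``excluded``.
    """
    ids = _id_cols(ann_df, id_cols)
    if not ids:
        raise ValueError("annotation table has no trial-identifying columns")
    off = (ann_df["label"] == OFF_OR_UNKNOWN).astype(float)
    res = (
        ann_df.assign(_off=off)
        .groupby(ids, sort=True)["_off"]
        .mean()
        .rename("off_fraction")
        .reset_index()
    )
    res["excluded"] = res["off_fraction"] > threshold
    return res


def apply_exclusions(df: pd.DataFrame, exclusions: pd.DataFrame, on=("subject", "trial")) -> pd.DataFrame:
    """Drop excluded trials from a co-recorded dataset of any method.

    The exclusion decided on the annotation stream propagates to the same
    (subject, trial) in every method's dataset; trials merely absent from a
    dataset are left untouched.
    """
    on = [c for c in on if c in df.columns and c in exclusions.columns]
    bad = exclusions.loc[exclusions["excluded"], on]
    merged = df.merge(bad.assign(_drop=True), on=on, how="left")
    return df.loc[merged["_drop"].isna().to_numpy()].reset_index(drop=True)


def annotation_agreement(primary, secondary) -> float:
    """Percent frame-level agreement between two aligned annotation streams."""
    a = np.asarray(primary)
    b = np.asarray(secondary)
    if a.shape != b.shape:
        raise ValueError("annotation streams differ in length")
    if a.size == 0:
        raise ValueError("empty annotation streams")
    return 100.0 * float(np.mean(a == b))
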