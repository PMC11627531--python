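"""Window-based effect sizes for gaze time courses.

Because cluster timings differ across datasets, three complementary
measures bracket the true effect: the *analysis-window* effect (averaged
over every bin of the preselected window; an underestimate, since it
includes effect-free bins), the *cluster-window* effect (averaged over the
bins of a significant cluster; descriptive of the detected effect), and
the *maximum* effect (the single best bin inside the cluster window; an
overestimate).

Two metrics are supported.  For chance-level fixation analyses the metric
is the grand-average proportion of target-quadrant looks, with the cluster
window defined as the temporal overlap of the positive horizontal-side and
vertical-side clusters.  For condition-effect analyses the metric is a
Cohen's d obtained from a window-level logit mixed model (same random
intercepts as the task analysis, plus a time-bin random intercept for the
multi-bin windows), converting the focal Wald z as d = 2 z / sqrt(n - p)
with p the number of fixed-effect parameters — a t-to-d conversion applied
with z in place of t, since binomial fits carry no residual df.  The df
convention is switchable via ``dof``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import Cluster
from .glmm import BinModelSpec, build_design, fit_logit_glmm

__all__ = ["EffectSizes", "proportion_effect_sizes", "window_cohens_d", "cluster_window_overlap"]


@dataclass
class EffectSizes:
    metric: str  # "proportion" or "cohens_d"
    analysis: float
    cluster: float | None
    maximum: float | None
    analysis_window_bins: tuple[int, int]
    cluster_window_bins: tuple[int, int] | None
    maximum_bin: int | None
    notes: str = ""


def _positive_bins(clusters: list[Cluster], significant_only: bool = True) -> set[int]:
    bins: set[int] = set()
    for c in clusters:
        if c.sign > 0 and (not significant_only or c.significant):
            bins.update(range(c.start_bin, c.end_bin + 1))
    return bins


def cluster_window_overlap(
    horizontal: list[Cluster], vertical: list[Cluster], significant_only: bool = True
) -> list[int]:
    """Bins where positive horizontal and vertical side clusters overlap."""
    return sorted(_positive_bins(horizontal, significant_only) & _positive_bins(vertical, significant_only))


def proportion_effect_sizes(
    binned: pd.DataFrame,
    response: str,
    analysis_bins: tuple[int, int],
    horizontal: list[Cluster],
    vertical: list[Cluster],
    significant_only: bool = True,
) -> EffectSizes:
    """Grand-average look proportions in the three windows.

    ``analysis_bins`` is half-open (lo, hi).  The cluster window is the
    overlap of the positive horizontal- and vertical-axis clusters; when the
    overlap is empty, the cluster and maximum measures are absent.
    """
    lo, hi = analysis_bins
    sel = binned.loc[(binned["bin"] >= lo) & (binned["bin"] < hi), ["bin", response]]
    analysis = float(sel[response].mean())
    overlap = [b for b in cluster_window_overlap(horizontal, vertical, significant_only) if lo <= b < hi]
    if not overlap:
        return EffectSizes("proportion", analysis, None, None, analysis_bins, None, None,
                           notes="no overlapping positive clusters")
    in_cluster = sel.loc[sel["bin"].isin(overlap)]
    cluster_val = float(in_cluster[response].mean())
    per_bin = in_cluster.groupby("bin")[response].mean()
    max_bin = int(per_bin.idxmax())
    return EffectSizes(
        "proportion",
        analysis,
        cluster_val,
        float(per_bin.max()),
        analysis_bins,
        (min(overlap), max(overlap) + 1),
        max_bin,
    )


def window_cohens_d(
    binned: pd.DataFrame,
    window_bins,
    spec: BinModelSpec,
    mode: str = "analysis",
    dof: str = "n_minus_p",
    **fit_kwargs,
):
    """Cohen's d for the focal condition effect over a bin window.

    ``mode`` "analysis" and "cluster" pool the listed bins and add a
    time-bin random intercept; "maximum" first selects the single bin with
    the largest raw condition difference in the response, then fits the
    per-bin model there.  Returns ``(d, info)``; d is None when the window
    model does not converge.
    """
    window_bins = list(window_bins)
    if not window_bins:
        raise ValueError("empty window")
    sub = binned.loc[binned["bin"].isin(window_bins) & binned[spec.response].notna()]
    if mode == "maximum":
        diffs = (
            sub.groupby(["bin", "condition"])[spec.response].mean().unstack("condition")
        )
        gap = (diffs.max(axis=1) - diffs.min(axis=1)).to_numpy()
        best = int(diffs.index[int(np.argmax(gap))])  # earliest argmax on ties
        sub = sub.loc[sub["bin"] == best]
        used_spec = spec
        info = {"bin": best}
    elif mode in ("analysis", "cluster"):
        used_spec = BinModelSpec(
            response=spec.response,
            fixed_effects=spec.fixed_effects,
            random_intercepts=tuple(spec.random_intercepts) + ("bin",),
            random_slopes=spec.random_slopes,
            focal=spec.focal,
        )
        info = {"bins": window_bins}
    else:
        raise ValueError("mode must be 'analysis', 'cluster' or 'maximum'")

    y, X, terms, names = build_design(sub, used_spec)
    fit = fit_logit_glmm(y, X, terms, term_names=names, **fit_kwargs)
    if not fit.converged:
        return None, {**info, "reason": fit.reason}
    focal = 0 if spec.focal == "intercept" else 1 + list(spec.fixed_effects).index(spec.focal)
    z = fit.beta[focal] / fit.se[focal]
    if dof == "n_minus_p":
        df_res = fit.n_obs - X.shape[1]
    elif dof == "n":
        df_res = fit.n_obs
    else:
        raise ValueError("dof must be 'n_minus_p' or 'n'")
    d = float(2.0 * z / np.sqrt(df_res))
    info.update({"z": float(z), "n_obs": fit.n_obs, "dof": df_res, "singular": fit.singular})
    return d, info
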