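"""End-to-end orchestration: simulate -> preprocess -> infer -> summarize.

The two analysis archetypes are implemented once and reused by every task:

* *chance-level analyses* (fixation-style): intercept-only models test
  whether looks to the target side of the screen exceed 50% chance on each
  axis, with target sides reshuffled per trial in the permutations;
  effect sizes are target-quadrant look proportions.
* *condition-effect analyses* (cohort/anticipatory-style): a sum-coded
  condition effect on target- or competitor-quadrant looks, with condition
  labels permuted within subjects; effect sizes are Cohen's d.

``run_pipeline`` glues the stages for one configured run and writes
delimited-text tables, JSON cluster/effect-size reports, and a manifest
carrying the seed and config digest, so a run is reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import cluster_permutation_test
from .config import RunConfig
from .effects import proportion_effect_sizes, window_cohens_d
from .glmm import BinModelSpec
from .preprocess import (
    QUADRANTS,
    RoiGeometry,
    apply_exclusions,
    bin_looks,
    exclude_trials,
)
from .sim import (
    SimResult,
    cohort_effects,
    default_methods,
    simulate_experiment,
    task_design,
    EffectSpec,
    ConditionEffect,
)

__all__ = [
    "add_design_responses",
    "binned_from_sim",
    "run_chance_analysis",
    "run_condition_analysis",
    "run_pipeline",
]


def add_design_responses(binned: pd.DataFrame, design_table: pd.DataFrame) -> pd.DataFrame:
    """Attach target/competitor responses derived from the trial design.

    Adds ``target_quad`` and ``competitor_quad`` (the binarized indicator of
    the trial's target/competitor quadrant) and ``target_side_h`` /
    ``target_side_v`` (the side indicator on the trial's target side).
    """
    cols = ["subject", "trial", "target_roi", "competitor_roi", "target_side_h", "target_side_v"]
    cols = [c for c in cols if c in design_table.columns or c in ("subject", "trial")]
    out = binned.merge(design_table[cols].drop_duplicates(), on=["subject", "trial"], how="left")
    quad_vals = out[list(QUADRANTS)].to_numpy()
    quad_idx = {q: i for i, q in enumerate(QUADRANTS)}

    def pick(roi_col):
        idx = out[roi_col].map(quad_idx).to_numpy()
        ok = pd.notna(idx)
        vals = np.full(len(out), np.nan)
        vals[ok] = quad_vals[np.arange(len(out))[ok], idx[ok].astype(int)]
        return vals

    if "target_roi" in out.columns:
        out["target_quad"] = pick("target_roi")
    if "competitor_roi" in out.columns:
        out["competitor_quad"] = pick("competitor_roi")
    if "target_side_h" in out.columns:
        out["target_side_h_look"] = np.where(
            out["target_side_h"] == "left", out["left"], out["right"]
        )
    if "target_side_v" in out.columns:
        out["target_side_v_look"] = np.where(
            out["target_side_v"] == "top", out["top"], out["bottom"]
        )
    return out


def binned_from_sim(
    simres: SimResult,
    window: tuple[int, int],
    bin_ms: int = 100,
    roi_threshold: float = 0.30,
    side_threshold: float = 0.50,
    exclusion_threshold: float = 0.50,
    valid_only: bool = False,
) -> dict[str, pd.DataFrame]:
    """Preprocess every channel of a simulated experiment.

    Applies the attention exclusion decided on the label (annotation)
    channel, if present, to all channels; trials missing from a channel
    (whole-trial loss) are not back-filled elsewhere.
    """
    geom = RoiGeometry(simres.design.center_fraction, simres.design.aspect_ratio)
    exclusions = None
    for name, ds in simres.datasets.items():
        if "label" in ds.columns:
            exclusions = exclude_trials(ds, threshold=exclusion_threshold,
                                        id_cols=["subject", "trial"])
            break
    out = {}
    for name, ds in simres.datasets.items():
        if exclusions is not None:
            ds = apply_exclusions(ds, exclusions)
        binned = bin_looks(
            ds,
            window,
            bin_ms=bin_ms,
            roi_threshold=roi_threshold,
            side_threshold=side_threshold,
            geom=geom,
            valid_only=valid_only,
        )
        out[name] = add_design_responses(binned, simres.design_table)
    return out


def run_chance_analysis(
    binned: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 2.0,
    alpha: float = 0.05,
    window_start_ms: int = 0,
    bin_ms: int = 100,
    **fit_kwargs,
):
    """Fixation-style analysis: target-side looks vs 50% chance on both axes.

    Runs the intercept-only cluster test separately for the horizontal and
    vertical axes (target-side reshuffle permutations) and computes the
    proportion effect sizes over their overlap.
    """
    results = {}
    for axis, resp, sides in (
        ("horizontal", "target_side_h_look", ("left", "right")),
        ("vertical", "target_side_v_look", ("top", "bottom")),
    ):
        spec = BinModelSpec(response=resp, fixed_effects=(), focal="intercept",
                            random_intercepts=("subject", "item"))
        results[axis] = cluster_permutation_test(
            binned,
            spec,
            scheme="target_side",
            n_perm=n_perm,
            threshold=threshold,
            seed=seed,
            alpha=alpha,
            side_cols=sides,
            window_start_ms=window_start_ms,
            bin_ms=bin_ms,
            **fit_kwargs,
        )
    bins = results["horizontal"].bins
    es = proportion_effect_sizes(
        binned,
        "target_quad",
        (min(bins), max(bins) + 1),
        results["horizontal"].clusters,
        results["vertical"].clusters,
    )
    return results, es


def run_condition_analysis(
    binned: pd.DataFrame,
    response: str,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 2.0,
    alpha: float = 0.05,
    window_start_ms: int = 0,
    bin_ms: int = 100,
    **fit_kwargs,
):
    """Cohort/anticipatory-style analysis: sum-coded condition effect.

    Returns the permutation result plus the three Cohen's-d effect sizes
    (cluster-window d absent when no significant cluster emerged).
    """
    spec = BinModelSpec(response=response, fixed_effects=("condition",), focal="condition",
                        random_intercepts=("subject", "item"))
    res = cluster_permutation_test(
        binned,
        spec,
        scheme="condition_within_subject",
        n_perm=n_perm,
        threshold=threshold,
        seed=seed,
        alpha=alpha,
        window_start_ms=window_start_ms,
        bin_ms=bin_ms,
        **fit_kwargs,
    )
    bins = res.bins
    d_analysis, _ = window_cohens_d(binned, bins, spec, mode="analysis", **fit_kwargs)
    sig = res.significant_clusters()
    d_cluster = None
    d_max = None
    max_info = {}
    if sig:
        top = max(sig, key=lambda c: c.z_sum)
        cl_bins = list(range(top.start_bin, top.end_bin + 1))
        d_cluster, _ = window_cohens_d(binned, cl_bins, spec, mode="cluster", **fit_kwargs)
        d_max, max_info = window_cohens_d(binned, cl_bins, spec, mode="maximum", **fit_kwargs)
    effect_sizes = {
        "metric": "cohens_d",
        "analysis": d_analysis,
        "cluster": d_cluster,
        "maximum": d_max,
        "maximum_bin": max_info.get("bin"),
    }
    return res, effect_sizes


def _default_effects(cfg: RunConfig) -> EffectSpec:
    if cfg.task == "phonemic_cohort":
        return cohort_effects(
            excess=cfg.cohort_excess,
            base_prob=cfg.cohort_base_prob,
            window=tuple(map(float, cfg.effect_window_ms)),
        )
    if cfg.task == "anticipatory":
        return EffectSpec(
            condition_effects={
                "constraining": ConditionEffect(latency_shift_ms=-250.0),
                "non_constraining": ConditionEffect(),
            }
        )
    return EffectSpec()


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """One reproducible run: simulate, preprocess, analyze, write outputs."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = task_design(
        cfg.task, center_fraction=cfg.center_fraction, aspect_ratio=cfg.aspect_ratio
    )
    effects = _default_effects(cfg)
    methods = {k: v for k, v in default_methods().items() if k in cfg.methods}
    simres = simulate_experiment(cfg.n_subjects, cfg.n_items, design, effects, methods, cfg.seed)
    binned = binned_from_sim(
        simres,
        cfg.window,
        bin_ms=cfg.bin_ms,
        roi_threshold=cfg.roi_threshold,
        side_threshold=cfg.side_threshold,
        exclusion_threshold=cfg.exclusion_threshold,
    )
    header = (
        f"# gazepipe {__version__} seed={cfg.seed} config={cfg.digest()}\n"
        "# times in ms from alignment zero; positions in screen proportion "
        "(origin top-left, y down)\n"
    )
    report: dict = {"seed": cfg.seed, "config_digest": cfg.digest(), "methods": {}}
    for name, b in binned.items():
        path = out / f"binned_{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            b.to_csv(fh, index=False)
        if cfg.task in ("phonemic_cohort", "anticipatory"):
            resp = "competitor_quad" if cfg.task == "phonemic_cohort" else "target_quad"
            res, es = run_condition_analysis(
                b, resp, n_perm=cfg.n_perm, seed=cfg.seed,
                threshold=cfg.z_threshold, alpha=cfg.alpha,
                window_start_ms=cfg.window_start_ms, bin_ms=cfg.bin_ms,
            )
            report["methods"][name] = {
                "clusters": res.summary().to_dict(orient="records"),
                "effect_sizes": es,
            }
        else:
            res, es = run_chance_analysis(
                b, n_perm=cfg.n_perm, seed=cfg.seed,
                threshold=cfg.z_threshold, alpha=cfg.alpha,
                window_start_ms=cfg.window_start_ms, bin_ms=cfg.bin_ms,
            )
            report["methods"][name] = {
                "clusters_horizontal": res["horizontal"].summary().to_dict(orient="records"),
                "clusters_vertical": res["vertical"].summary().to_dict(orient="records"),
                "effect_sizes": asdict(es),
            }
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "config": cfg.to_dict(),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "clusters.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    manifest["outputs"] = sorted(p.name for p in out.iterdir())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
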