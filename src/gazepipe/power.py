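"""Simulation-based power analysis around the observed peak effect.

The procedure mirrors a post-hoc mixed-model power analysis: (1) locate the
3-bin window centered on the bin with the largest standardized condition
effect; (2) collapse each trial to the proportion of window bins with
competitor looks and binarize at 30%; (3) fit the *observed-effect model*,
a logit mixed model with a sum-coded condition effect and a maximal
(uncorrelated) random-effects structure — by-subject and by-item intercepts
and condition slopes — simplifying stepwise on non-convergence; (4) for
each sample size on a grid, simulate many datasets from the fitted model
(fresh subject and item effects drawn from the fitted variance components,
item set size preserved), refit, and report power as the fraction of
simulations whose focal |z| exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .glmm import GlmmFit, RandomTerm, fit_logit_glmm

__all__ = [
    "PowerCurve",
    "ObservedEffectModel",
    "find_peak_window",
    "collapse_and_binarize",
    "fit_observed_effect_model",
    "simulate_power",
]


def find_peak_window(d_series) -> tuple[int, int, int]:
    """The 3 consecutive bins around the largest effect size.

    Returns bin indices (lo, mid, hi), inclusive.  Ties take the earliest
    argmax; at a boundary the window is clipped inward so it keeps 3 bins.
    """
    d = np.asarray(d_series, float)
    if len(d) < 3:
        raise ValueError("need at least 3 bins")
    mid = int(np.nanargmax(d))
    lo = min(max(mid - 1, 0), len(d) - 3)
    return lo, mid, lo + 2


def collapse_and_binarize(
    binned: pd.DataFrame,
    window_bins,
    response: str,
    threshold: float = 0.30,
) -> tuple[pd.DataFrame, int]:
    """One binary response per trial from the look proportion in a window.

    The per-trial proportion is computed over the window's non-missing bin
    indicators; the response is 1 iff the proportion is >= ``threshold``.
    Trials with no non-missing window bin are dropped; their count is
    returned alongside.
    """
    window_bins = list(window_bins)
    key = [c for c in ("subject", "item", "trial", "condition", "method", "experiment")
           if c in binned.columns]
    sel = binned.loc[binned["bin"].isin(window_bins)]
    prop = sel.groupby(key, sort=True)[response].mean().rename("prop").reset_index()
    dropped = int(prop["prop"].isna().sum())
    prop = prop.dropna(subset=["prop"])
    prop["response"] = (prop["prop"] >= threshold).astype(float)
    return prop, dropped


@dataclass
class ObservedEffectModel:
    """Fitted observed-effect model plus the structure it converged with."""

    fit: GlmmFit
    structure: str  # "maximal", "subject_slope", "intercepts"
    n_subjects: int
    n_items: int
    ladder_log: list[str] = field(default_factory=list)

    @property
    def beta0(self) -> float:
        return float(self.fit.beta[0])

    @property
    def beta_condition(self) -> float:
        return float(self.fit.beta[1])

    @property
    def z_condition(self) -> float:
        return self.fit.z(1)

    def variance_components(self) -> dict[str, float]:
        return dict(self.fit.sigma)


_LADDERS = [
    ("maximal", (("subject", True), ("item", True))),
    ("subject_slope", (("subject", True), ("item", False))),
    ("intercepts", (("subject", False), ("item", False))),
]


def _build_terms(subj, item, cond, slopes_subject: bool, slopes_item: bool):
    terms = [RandomTerm.intercept("subject", subj), RandomTerm.intercept("item", item)]
    if slopes_subject:
        terms.append(RandomTerm.slope("subject:condition", subj, cond))
    if slopes_item:
        terms.append(RandomTerm.slope("item:condition", item, cond))
    return terms


def fit_observed_effect_model(trials: pd.DataFrame, **fit_kwargs) -> ObservedEffectModel:
    """Fit the condition effect on trial-level binary responses.

    ``trials`` has one row per trial: subject, item, condition (two levels,
    sum-coded +1/-1 by sorted label), response (0/1).  Starts from the
    maximal uncorrelated structure (intercepts and condition slopes by
    subject and item) and drops slope terms stepwise on non-convergence.
    """
    from .glmm import sum_code

    if trials["subject"].nunique() < 2 or trials["item"].nunique() < 2:
        raise ValueError("need at least 2 subjects and 2 items")
    y = trials["response"].to_numpy(float)
    cond = sum_code(trials["condition"].to_numpy())
    X = np.column_stack([np.ones(len(y)), cond])
    subj = trials["subject"].to_numpy()
    item = trials["item"].to_numpy()
    log = []
    for name, ((_, ss), (_, si)) in _LADDERS:
        terms = _build_terms(subj, item, cond, ss, si)
        fit = fit_logit_glmm(y, X, terms, term_names=["intercept", "condition"], **fit_kwargs)
        if fit.converged:
            log.append(f"{name}: converged" + (" (singular)" if fit.singular else ""))
            return ObservedEffectModel(
                fit, name, trials["subject"].nunique(), trials["item"].nunique(), log
            )
        log.append(f"{name}: {fit.reason}")
    raise RuntimeError("observed-effect model did not converge at any ladder step: " + "; ".join(log))


@dataclass
class PowerCurve:
    n_grid: list[int]
    power: list[float]
    mc_se: list[float]
    n_sim: int
    z_threshold: float
    refit_failures: list[int]
    beta_condition: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_subjects": self.n_grid,
                "power": self.power,
                "mc_se": self.mc_se,
                "refit_failures": self.refit_failures,
            }
        )


def simulate_power(
    model: ObservedEffectModel,
    n_grid=(20, 30, 40, 50, 60),
    n_sim: int = 1000,
    z_threshold: float = 2.0,
    seed: int = 0,
    beta_override: float | None = None,
    trials_per_condition: int | None = None,
    **fit_kwargs,
) -> PowerCurve:
    """Monte-Carlo power for the condition effect across sample sizes.

    Each simulated dataset draws fresh subject (and item) effects from the
    fitted variance components, keeps the item-set size and per-subject
    trial counts of the original design, simulates binary responses from
    the fitted fixed effects (``beta_override`` substitutes the condition
    coefficient, e.g. 0 for null calibration), and refits the model
    structure the observed fit converged with.  Power at each n is the
    fraction of converged refits with focal |z| > ``z_threshold``; refit
    failures are counted separately.
    """
    if not model.fit.converged:
        raise ValueError("observed-effect model must be converged")
    sig = model.variance_components()
    beta0 = model.beta0
    beta_c = model.beta_condition if beta_override is None else float(beta_override)
    n_items = model.n_items
    per_cond = trials_per_condition if trials_per_condition is not None else n_items
    ss = (("subject", True), ("item", True))
    structure = dict(_LADDERS)[model.structure]

    n_grid = sorted(int(n) for n in n_grid)
    power, mc_se, failures = [], [], []
    for gi, n in enumerate(n_grid):
        hits = 0
        fails = 0
        for sim in range(n_sim):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gi, sim)))
            u_s = rng.normal(0.0, sig.get("subject", 0.0), n)
            w_i = rng.normal(0.0, sig.get("item", 0.0), n_items)
            s_s = rng.normal(0.0, sig.get("subject:condition", 0.0), n)
            s_i = rng.normal(0.0, sig.get("item:condition", 0.0), n_items)
            # balanced design: each subject sees each item in both conditions,
            # trimmed to per_cond trials per condition
            subj = np.repeat(np.arange(n), n_items * 2)
            item = np.tile(np.repeat(np.arange(n_items), 2), n)
            cond = np.tile(np.array([1.0, -1.0]), n * n_items)
            if per_cond < n_items:
                keep = np.zeros(len(subj), bool)
                for s in range(n):
                    base = s * n_items * 2
                    keep[base : base + per_cond * 2] = True
                subj, item, cond = subj[keep], item[keep], cond[keep]
            eta = beta0 + beta_c * cond + u_s[subj] + w_i[item] + cond * (s_s[subj] + s_i[item])
            y = (rng.random(len(eta)) < expit(eta)).astype(float)
            X = np.column_stack([np.ones(len(y)), cond])
            terms = _build_terms(subj, item, cond, structure[0][1], structure[1][1])
            # warm-start every refit at the generating parameters: the same
            # deterministic settings apply to each simulated dataset
            start = np.array([max(sig.get(t.name, 0.3), 5e-2) for t in terms])
            kw = dict(start_sigma=start, start_beta=np.array([beta0, beta_c]), fast=True)
            kw.update(fit_kwargs)
            fit = fit_logit_glmm(y, X, terms, **kw)
            if not fit.converged:
                fails += 1
                continue
            if abs(fit.z(1)) > z_threshold:
                hits += 1
        n_ok = n_sim - fails
        p = hits / n_ok if n_ok else np.nan
        power.append(float(p))
        mc_se.append(float(np.sqrt(p * (1 - p) / n_ok)) if n_ok else np.nan)
        failures.append(fails)
    return PowerCurve(n_grid, power, mc_se, n_sim, z_threshold, failures, beta_c)
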