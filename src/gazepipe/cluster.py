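"""Cluster-mass permutation inference over per-bin mixed-model z series.

The per-bin |z| series from :mod:`gazepipe.glmm` is thresholded at |z| > 2;
maximal runs of adjacent supra-threshold bins with the same sign form
clusters, each scored by the z-sum (the sum of |z| over its bins).  The
null distribution is built by re-running the identical scan — including the
carry-forward fallback rules — on datasets whose labels have been shuffled
under one of four exchangeability schemes:

* ``condition_within_subject`` — condition labels permuted across each
  subject's trials (individual dataset analyses);
* ``method_within_subject`` — which paired dataset carries which method
  label is reassigned per subject (intra-experiment comparisons);
* ``experiment_between_subjects`` — experiment labels shuffled across
  subjects (inter-experiment comparisons);
* ``target_side`` — each trial's designated target side on one screen axis
  is redrawn and the side-look response re-derived against the new side
  (fixation-style chance analyses).

By default each permutation contributes its *maximum* cluster z-sum (0 when
no cluster forms), the max-statistic convention that controls family-wise
error; ``null_statistic="all"`` instead pools every null cluster's z-sum.
A cluster's p-value is the proportion of null statistics greater than or
equal to its z-sum; p = 0 is reported as "< 0.001".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import BinModelResult, BinModelSpec, fit_logit_glmm, RandomTerm, sum_code

__all__ = [
    "Cluster",
    "PermutationResult",
    "SCHEMES",
    "find_clusters",
    "permute_labels",
    "cluster_permutation_test",
    "scan_dataset",
]

SCHEMES = (
    "condition_within_subject",
    "method_within_subject",
    "experiment_between_subjects",
    "target_side",
)


@dataclass
class Cluster:
    start_bin: int
    end_bin: int  # inclusive
    sign: int
    z_sum: float
    p_value: float | None = None
    p_str: str = ""
    significant: bool | None = None

    def span_ms(self, bin_ms: int = 100, window_start_ms: int = 0) -> tuple[int, int]:
        """Inclusive ms span, reported the conventional way (e.g. 100-399 ms)."""
        lo = window_start_ms + self.start_bin * bin_ms
        hi = window_start_ms + (self.end_bin + 1) * bin_ms - 1
        return lo, hi


def find_clusters(z, threshold: float = 2.0, bins=None) -> list[Cluster]:
    """Maximal runs of adjacent bins with |z| > threshold and a shared sign."""
    z = np.asarray(z, float)
    if bins is None:
        bins = np.arange(len(z))
    bins = np.asarray(bins)
    sign = np.where(z > threshold, 1, np.where(z < -threshold, -1, 0))
    clusters: list[Cluster] = []
    i = 0
    while i < len(z):
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(z) and sign[j + 1] == sign[i]:
            j += 1
        clusters.append(
            Cluster(int(bins[i]), int(bins[j]), int(sign[i]), float(np.abs(z[i : j + 1]).sum()))
        )
        i = j + 1
    return clusters


# ---------------------------------------------------------------------------
# prepared scan: one structure reused across all permutations


class _PreparedScan:
    """Per-bin design data with labels factored out at the trial level.

    Permutations only relabel trials (or redraw target sides), so the
    response vectors and random-effect structure are built once; each scan
    plugs in a per-trial coded label vector (or side draw) and refits.
    """

    def __init__(
        self,
        binned: pd.DataFrame,
        spec: BinModelSpec,
        bins=None,
        side_response: tuple[str, str] | None = None,
        fit_kwargs: dict | None = None,
    ):
        self.spec = spec
        self.fit_kwargs = fit_kwargs or {}
        self.side_response = side_response
        self.bins = list(bins) if bins is not None else sorted(binned["bin"].unique())
        if not self.bins:
            raise ValueError("empty analysis window")

        # trial slots: one per recorded trial per method dataset
        slot_cols = [c for c in ("subject", "trial", "method") if c in binned.columns]
        slot_key = binned[slot_cols].apply(tuple, axis=1)
        slot_codes, slot_uniq = pd.factorize(slot_key, sort=True)
        self.n_slots = len(slot_uniq)
        slots = binned.loc[~slot_key.duplicated()].copy()
        slots["_slot"] = slot_codes[~slot_key.duplicated().to_numpy()]
        slots = slots.sort_values("_slot")
        self.slot_subject = pd.factorize(slots["subject"], sort=True)[0]
        self.slot_trial = slots["trial"].to_numpy()
        self.slot_labels: dict[str, np.ndarray] = {}
        for col in ("condition", "method", "experiment"):
            if col in slots.columns:
                self.slot_labels[col] = slots[col].to_numpy()
        # trial groups (subject, trial) spanning paired method slots
        if "method" in slot_cols:
            tkey = list(zip(slots["subject"], slots["trial"]))
            self.slot_trialgroup, self.trialgroups = pd.factorize(pd.Series(tkey), sort=True)
        else:
            self.slot_trialgroup = np.arange(self.n_slots)
            self.trialgroups = slot_uniq
        # subject of each trial group (constant within group by construction)
        self.tg_subject = np.full(len(self.trialgroups), -1)
        self.tg_subject[self.slot_trialgroup] = self.slot_subject
        self.subject_tg_idx = [
            np.nonzero(self.tg_subject == s)[0] for s in np.unique(self.tg_subject)
        ]

        self.focal = (
            0 if spec.focal == "intercept" else 1 + list(spec.fixed_effects).index(spec.focal)
        )

        # pilot fits (variance estimates and joint modes from an observed-data
        # scan) warm-start every subsequent scan with a reduced optimizer
        # budget; the same settings apply to every permuted scan.
        self._pilot: list[tuple | None] | None = None
        # per-bin fixed variance components (dict term name -> sd), applied
        # identically to the observed and every permuted scan
        self._fixed_sigma: list[dict | None] | None = None

        resp_cols = [spec.response] if side_response is None else list(side_response)
        self.per_bin = []
        for b in self.bins:
            sub = binned.loc[binned["bin"] == b]
            mask = sub[resp_cols].notna().all(axis=1).to_numpy()
            sub = sub.loc[mask]
            entry = {
                "n": len(sub),
                "slot": slot_codes[binned["bin"].to_numpy() == b][mask],
                "responses": {c: sub[c].to_numpy(float) for c in resp_cols},
                "n_subjects": sub["subject"].nunique(),
                "terms": [
                    RandomTerm.intercept(g, sub[g].to_numpy()) for g in spec.random_intercepts
                ]
                if len(sub)
                else [],
                "slopes_src": {g: sub[g].to_numpy() for g, _f in spec.random_slopes},
            }
            self.per_bin.append(entry)

        # coded fixed-effect values per slot (observed labels)
        self.observed_codes = {
            name: self._code_labels(name, self.slot_labels[name])
            for name in self._base_factors()
        }

    def _base_factors(self):
        out = []
        for fe in self.spec.fixed_effects:
            for name in fe.split(":"):
                if name not in out:
                    out.append(name)
        return out

    def _code_labels(self, name: str, labels: np.ndarray) -> np.ndarray:
        levels = sorted(pd.unique(self.slot_labels[name]))
        return sum_code(labels, levels)

    def scan(
        self,
        codes: dict[str, np.ndarray] | None = None,
        side: np.ndarray | None = None,
        record_pilot: bool = False,
    ) -> list[BinModelResult]:
        """Run the per-bin fits with the given per-slot coded labels.

        ``side`` (0 = first side column, 1 = second) selects the response
        per trial group for the target-side scheme.  With
        ``record_pilot=True`` the full-budget fits are stored as warm
        starts for subsequent (permutation) scans.
        """
        spec = self.spec
        codes = codes if codes is not None else self.observed_codes
        results: list[BinModelResult] = []
        if record_pilot:
            self._pilot = [None] * len(self.bins)
        prev = (0.0, np.nan, 0.0)
        for bi, (b, entry) in enumerate(zip(self.bins, self.per_bin)):
            n = entry["n"]
            fit = None
            if n and entry["n_subjects"] >= 2:
                slot = entry["slot"]
                if self.side_response is not None:
                    c0, c1 = self.side_response
                    if side is None:
                        y = entry["responses"][c0]
                    else:
                        pick = side[self.slot_trialgroup[slot]]
                        y = np.where(pick == 0, entry["responses"][c0], entry["responses"][c1])
                else:
                    y = entry["responses"][spec.response]
                if y.min() == y.max():
                    fit = None  # no variation: inestimable, triggers fallback
                else:
                    cols = [np.ones(n)]
                    fvals = {name: codes[name][slot] for name in codes}
                    for fe in spec.fixed_effects:
                        if ":" in fe:
                            a, bb = fe.split(":")
                            cols.append(fvals[a] * fvals[bb])
                        else:
                            cols.append(fvals[fe])
                    X = np.column_stack(cols)
                    terms = list(entry["terms"])
                    for g, fac in spec.random_slopes:
                        terms.append(
                            RandomTerm.slope(f"{g}:{fac}", entry["slopes_src"][g], fvals[fac])
                        )
                    kw = dict(self.fit_kwargs)
                    if self._fixed_sigma is not None and self._fixed_sigma[bi] is not None:
                        kw.setdefault("fix_sigma", self._fixed_sigma[bi])
                    if not record_pilot and self._pilot is not None:
                        warm = self._pilot[bi]
                        if warm is not None:
                            sg = np.array([max(warm[0].get(t.name, 0.5), 1e-3) for t in terms])
                            kw.setdefault("start_sigma", sg)
                            kw.setdefault("start_beta", warm[1])
                            kw.setdefault("start_u", warm[2])
                            kw.setdefault("fast", True)
                    fit = fit_logit_glmm(y, X, terms, **kw)
                    if record_pilot and fit.converged:
                        self._pilot[bi] = (dict(fit.sigma), fit.beta.copy(), fit.u)
            if fit is not None and fit.converged:
                est, se = float(fit.beta[self.focal]), float(fit.se[self.focal])
                z = est / se if se > 0 else 0.0
                results.append(BinModelResult(b, est, se, z, True, fit.singular, False, n))
                prev = (est, se, z)
            else:
                est, se, z = prev
                reason = fit.reason if fit is not None else "inestimable bin"
                results.append(BinModelResult(b, est, se, z, False, False, True, n, reason))
        return results

    def estimate_null_variances(self) -> list[dict | None]:
        """Per-bin variance components from an intercept-only null model.

        For the label-shuffling schemes the null model (no fixed effects,
        random-term regressors at their observed values) does not depend on
        the shuffled labels, so fixing its variance estimates across the
        observed and all permuted scans preserves exchangeability while
        making each scan a single penalized-likelihood solve.
        """
        out: list[dict | None] = []
        for entry in self.per_bin:
            sig = None
            n = entry["n"]
            if n and entry["n_subjects"] >= 2:
                y = (
                    entry["responses"][self.spec.response]
                    if self.side_response is None
                    else entry["responses"][self.side_response[0]]
                )
                if y.min() != y.max():
                    X = np.ones((n, 1))
                    slot = entry["slot"]
                    terms = list(entry["terms"])
                    for g, fac in self.spec.random_slopes:
                        fv = self.observed_codes[fac][slot]
                        terms.append(RandomTerm.slope(f"{g}:{fac}", entry["slopes_src"][g], fv))
                    fit = fit_logit_glmm(y, X, terms, **self.fit_kwargs)
                    if fit.converged:
                        sig = {k: (0.0 if v < 1e-3 else float(v)) for k, v in fit.sigma.items()}
            out.append(sig)
        return out


def _fill_nearest(values: list) -> list:
    """Fill None entries with the nearest non-None neighbor (by bin index).

    Bins whose null model is inestimable (e.g. a saturated response) borrow
    the variance components of the nearest estimable bin, keeping every
    permuted scan on the fast fixed-variance path.
    """
    idx = [i for i, v in enumerate(values) if v is not None]
    if not idx:
        return values
    return [values[min(idx, key=lambda k: abs(k - i))] if v is None else v
            for i, v in enumerate(values)]


def scan_dataset(binned, spec, bins=None, **fit_kwargs):
    """Observed-data scan through the same prepared path the permutations use."""
    prep = _PreparedScan(binned, spec, bins=bins, fit_kwargs=fit_kwargs)
    return prep.scan()


# ---------------------------------------------------------------------------
# label shuffling


def _permute_slot_codes(prep: _PreparedScan, scheme: str, factor: str, rng) -> np.ndarray:
    """Return a permuted per-slot coded (+/-1) vector for ``factor``."""
    base = prep.observed_codes[factor]
    out = base.copy()
    if scheme == "condition_within_subject":
        # permute condition labels across each subject's trial groups
        tg_code = np.zeros(len(prep.trialgroups))
        tg_code[prep.slot_trialgroup] = base
        for idx in prep.subject_tg_idx:
            tg_code[idx] = tg_code[idx[rng.permutation(len(idx))]]
        out = tg_code[prep.slot_trialgroup]
    elif scheme == "method_within_subject":
        # reassign which of the paired datasets carries which method label
        for s in np.unique(prep.slot_subject):
            if rng.random() < 0.5:
                m = prep.slot_subject == s
                out[m] = -out[m]
    elif scheme == "experiment_between_subjects":
        subjects = np.unique(prep.slot_subject)
        per_subj = np.empty(len(subjects))
        for i, s in enumerate(subjects):
            per_subj[i] = base[prep.slot_subject == s][0]
        per_subj = per_subj[rng.permutation(len(per_subj))]
        lut = dict(zip(subjects, per_subj))
        out = np.array([lut[s] for s in prep.slot_subject])
    else:
        raise ValueError(f"unknown label scheme {scheme!r}")
    return out


def permute_labels(
    binned: pd.DataFrame,
    scheme: str,
    rng: np.random.Generator,
    factor: str | None = None,
    side_cols: tuple[str, str] = ("left", "right"),
    response: str | None = None,
) -> pd.DataFrame:
    """Shuffle labels on a binned table under one exchangeability scheme.

    Observed responses are never altered, except that the target-side scheme
    re-derives the side-look response against each trial's newly drawn side.
    """
    df = binned.copy()
    if scheme == "target_side":
        if response is None:
            raise ValueError("target_side scheme needs the response column name")
        key = [c for c in ("subject", "trial") if c in df.columns]
        trials = df[key].drop_duplicates()
        draw = rng.integers(0, 2, len(trials))
        trials = trials.assign(_side=draw)
        df = df.merge(trials, on=key)
        df[response] = np.where(df["_side"] == 0, df[side_cols[0]], df[side_cols[1]])
        return df.drop(columns="_side")

    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if factor is None:
        factor = {
            "condition_within_subject": "condition",
            "method_within_subject": "method",
            "experiment_between_subjects": "experiment",
        }[scheme]
    if scheme == "condition_within_subject":
        key = [c for c in ("subject", "trial") if c in df.columns]
        trials = df[key + [factor]].drop_duplicates(subset=key).reset_index(drop=True)
        permuted = []
        for s, grp in trials.groupby("subject", sort=False):
            vals = grp[factor].to_numpy()
            permuted.append(grp.assign(**{factor: vals[rng.permutation(len(vals))]}))
        trials = pd.concat(permuted)
        df = df.drop(columns=factor).merge(trials, on=key)
    elif scheme == "method_within_subject":
        out = df[factor].copy()
        for s, grp in df.groupby("subject", sort=False):
            methods = pd.unique(grp[factor])
            perm = dict(zip(methods, methods[rng.permutation(len(methods))]))
            out.loc[grp.index] = grp[factor].map(perm)
        df[factor] = out
    elif scheme == "experiment_between_subjects":
        subj = df[["subject", factor]].drop_duplicates(subset="subject")
        labels = subj[factor].to_numpy()
        subj = subj.assign(**{factor: labels[rng.permutation(len(labels))]})
        df = df.drop(columns=factor).merge(subj, on="subject")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return df


# ---------------------------------------------------------------------------
# the permutation test


@dataclass
class PermutationResult:
    clusters: list[Cluster]
    bin_results: list[BinModelResult]
    null_stats: np.ndarray
    n_perm: int
    scheme: str
    threshold: float
    alpha: float
    bins: list[int]
    null_statistic: str = "max"
    bin_ms: int = 100
    window_start_ms: int = 0

    @property
    def z(self) -> np.ndarray:
        return np.array([r.z for r in self.bin_results])

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            lo, hi = c.span_ms(self.bin_ms, self.window_start_ms)
            rows.append(
                dict(
                    start_ms=lo, end_ms=hi, sign=c.sign, z_sum=c.z_sum,
                    p=c.p_value, p_str=c.p_str, significant=c.significant,
                )
            )
        return pd.DataFrame(rows)


def _enumerate_assignments(prep: _PreparedScan, scheme: str, factor: str, limit: int):
    """Yield every distinct label assignment (exhaustive null) for tiny data."""
    if scheme == "condition_within_subject":
        tg_subject = np.full(len(prep.trialgroups), -1)
        base = prep.observed_codes[factor]
        tg_code = np.zeros(len(prep.trialgroups))
        for slot in range(prep.n_slots):
            tg_subject[prep.slot_trialgroup[slot]] = prep.slot_subject[slot]
            tg_code[prep.slot_trialgroup[slot]] = base[slot]
        subj_groups = [np.nonzero(tg_subject == s)[0] for s in np.unique(tg_subject)]
        per_subject = [
            sorted(set(itertools.permutations(tg_code[idx]))) for idx in subj_groups
        ]
        total = int(np.prod([len(p) for p in per_subject]))
        if total > limit:
            raise ValueError(f"exhaustive enumeration too large ({total} assignments)")
        for combo in itertools.product(*per_subject):
            tg = tg_code.copy()
            for idx, vals in zip(subj_groups, combo):
                tg[idx] = vals
            yield {"codes": {factor: tg[prep.slot_trialgroup]}, "side": None}
    elif scheme == "target_side":
        n_tg = len(prep.trialgroups)
        if 2**n_tg > limit:
            raise ValueError(f"exhaustive enumeration too large (2^{n_tg} assignments)")
        for combo in itertools.product((0, 1), repeat=n_tg):
            yield {"codes": None, "side": np.array(combo)}
    else:
        raise ValueError(f"exhaustive mode not supported for scheme {scheme!r}")


def cluster_permutation_test(
    binned: pd.DataFrame,
    spec: BinModelSpec,
    scheme: str,
    n_perm: int = 1000,
    threshold: float = 2.0,
    seed: int = 0,
    alpha: float = 0.05,
    bins=None,
    factor: str | None = None,
    side_cols: tuple[str, str] = ("left", "right"),
    null_statistic: str = "max",
    exhaustive: bool = False,
    exhaustive_limit: int = 100_000,
    bin_ms: int = 100,
    window_start_ms: int = 0,
    reestimate_variance: bool = False,
    **fit_kwargs,
) -> PermutationResult:
    """Cluster-mass permutation test on a binned look dataset.

    The observed scan and every permuted scan run through the identical
    prepared path (same carry-forward rules).  By default the per-bin
    variance components are estimated once (from an intercept-only null
    model, which the label shuffles leave untouched) and held fixed across
    the observed and all permuted scans; ``reestimate_variance=True``
    re-profiles them in every scan instead.  Permutation streams are
    derived from ``seed`` by counter, so results are reproducible and
    order-independent.  With ``exhaustive=True`` the full null distribution
    is enumerated (tiny datasets only) instead of sampled.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if factor is None and scheme != "target_side":
        factor = {
            "condition_within_subject": "condition",
            "method_within_subject": "method",
            "experiment_between_subjects": "experiment",
        }[scheme]

    side_response = tuple(side_cols) if scheme == "target_side" else None
    prep = _PreparedScan(binned, spec, bins=bins, side_response=side_response, fit_kwargs=fit_kwargs)

    if scheme == "target_side":
        # observed scan: the recorded response column (derived by the caller
        # from each trial's true target side) through the plain path
        obs_prep = _PreparedScan(binned, spec, bins=bins, fit_kwargs=fit_kwargs)
        if reestimate_variance:
            bin_results = obs_prep.scan(record_pilot=True)
            prep._pilot = obs_prep._pilot  # warm-start permuted scans
        else:
            fixed = _fill_nearest(obs_prep.estimate_null_variances())
            obs_prep._fixed_sigma = fixed
            prep._fixed_sigma = fixed
            bin_results = obs_prep.scan(record_pilot=True)
            prep._pilot = obs_prep._pilot
    else:
        if reestimate_variance:
            bin_results = prep.scan(record_pilot=True)
        else:
            prep._fixed_sigma = _fill_nearest(prep.estimate_null_variances())
            bin_results = prep.scan(record_pilot=True)
    z = np.array([r.z for r in bin_results])
    clusters = find_clusters(z, threshold, bins=prep.bins)

    null_stats: list[float] = []
    if exhaustive:
        assignments = _enumerate_assignments(prep, scheme, factor or "", exhaustive_limit)
    else:
        def _sampled():
            for i in range(n_perm):
                rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
                if scheme == "target_side":
                    yield {"codes": None, "side": rng.integers(0, 2, len(prep.trialgroups))}
                else:
                    yield {
                        "codes": {factor: _permute_slot_codes(prep, scheme, factor, rng)},
                        "side": None,
                    }
        assignments = _sampled()

    for a in assignments:
        codes = dict(prep.observed_codes)
        if a["codes"]:
            codes.update(a["codes"])
        res = prep.scan(codes=codes, side=a["side"])
        zperm = np.array([r.z for r in res])
        cl = find_clusters(zperm, threshold, bins=prep.bins)
        if null_statistic == "max":
            null_stats.append(max((c.z_sum for c in cl), default=0.0))
        elif null_statistic == "all":
            null_stats.extend([c.z_sum for c in cl] or [0.0])
        else:
            raise ValueError("null_statistic must be 'max' or 'all'")

    null = np.asarray(null_stats)
    n_eff = len(null)
    for c in clusters:
        count = int(np.sum(null >= c.z_sum))
        c.p_value = count / n_eff
        c.p_str = "< 0.001" if count == 0 else f"= {c.p_value:.3f}"
        c.significant = c.p_value < alpha
    return PermutationResult(
        clusters=clusters,
        bin_results=bin_results,
        null_stats=null,
        n_perm=n_eff if exhaustive else n_perm,
        scheme=scheme,
        threshold=threshold,
        alpha=alpha,
        bins=prep.bins,
        null_statistic=null_statistic,
        bin_ms=bin_ms,
        window_start_ms=window_start_ms,
    )
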