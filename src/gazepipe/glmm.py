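"""Binomial-logit mixed-effects models for per-time-bin gaze analyses.

Every time-course inference in this package reduces to fitting, per 100 ms
bin, a logistic regression with crossed Gaussian random intercepts (and
optionally random slopes) for subjects and items, and extracting the Wald
``z`` of a focal term.  The fitter below maximizes the Laplace-approximate
marginal likelihood, the same objective family as ``lme4::glmer``:

    y_i ~ Bernoulli(logit^-1(eta_i)),  eta = X beta + sum_k Z_k u_k,
    u_k ~ N(0, sigma_k^2 I).

Random-effect terms are independent (diagonal covariance); intercept-slope
correlations are not estimated.  For fixed variance parameters the joint
mode of (beta, u) is found by Newton's method on the penalized
log-likelihood; the marginal likelihood is then profiled over the
variance parameters by Nelder-Mead on the log-SD scale.

A Gauss-Hermite exact-likelihood fitter for a single grouping factor is
provided as an independent oracle for tests on tiny data; it plays no role
in the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

__all__ = [
    "RandomTerm",
    "BinModelSpec",
    "GlmmFit",
    "BinModelResult",
    "fit_logit_glmm",
    "fit_bin_model",
    "scan_window",
    "build_design",
    "sum_code",
    "fit_exact_single_grouping",
]

_SINGULAR_SD = 1e-3  # variance < 1e-6 counts as singular, not as failure
_MAX_ABS_BETA = 15.0
_MAX_SE = 100.0


# ---------------------------------------------------------------------------
# design construction


def sum_code(values: Sequence, levels: Sequence | None = None) -> np.ndarray:
    """Sum-code a two-level factor as +/-1 (first sorted level -> +1)."""
    arr = np.asarray(values)
    if levels is None:
        levels = sorted(pd.unique(arr))
    if len(levels) != 2:
        raise ValueError(f"sum coding requires exactly 2 levels, got {list(levels)}")
    out = np.where(arr == levels[0], 1.0, -1.0)
    if not np.isin(arr, levels).all():
        raise ValueError("values outside declared factor levels")
    return out


@dataclass(frozen=True)
class RandomTerm:
    """One independent random-effect term (intercept or slope).

    ``codes`` maps each observation to a level 0..n_levels-1; ``values`` is
    the regressor multiplying the effect (all ones for an intercept).
    """

    name: str
    codes: np.ndarray
    n_levels: int
    values: np.ndarray

    @staticmethod
    def intercept(name: str, labels: Sequence) -> "RandomTerm":
        codes, uniq = pd.factorize(np.asarray(labels), sort=True)
        return RandomTerm(name, codes.astype(np.int64), len(uniq), np.ones(len(codes)))

    @staticmethod
    def slope(name: str, labels: Sequence, x: np.ndarray) -> "RandomTerm":
        codes, uniq = pd.factorize(np.asarray(labels), sort=True)
        return RandomTerm(name, codes.astype(np.int64), len(uniq), np.asarray(x, float))


@dataclass(frozen=True)
class BinModelSpec:
    """Model specification for the per-bin analyses.

    ``fixed_effects`` are names of two-level factor columns (sum-coded +/-1);
    an interaction is written ``"a:b"``.  ``focal`` is the term whose z is
    extracted: ``"intercept"`` for the chance-level analyses, otherwise a
    fixed-effect name.
    """

    response: str
    fixed_effects: tuple[str, ...] = ()
    random_intercepts: tuple[str, ...] = ("subject", "item")
    random_slopes: tuple[tuple[str, str], ...] = ()  # (group column, factor)
    focal: str = "intercept"

    def __post_init__(self):
        terms = ("intercept",) + self.fixed_effects
        if self.focal not in terms:
            raise ValueError(f"focal term {self.focal!r} not in model terms {terms}")


def build_design(df: pd.DataFrame, spec: BinModelSpec):
    """Build (y, X, terms, colnames) from a long-format bin table."""
    y = np.asarray(df[spec.response], float)
    n = len(y)
    cols = [np.ones(n)]
    names = ["intercept"]
    coded: dict[str, np.ndarray] = {}

    def factor(name: str) -> np.ndarray:
        if name not in coded:
            if ":" in name:
                a, b = name.split(":")
                coded[name] = factor(a) * factor(b)
            else:
                coded[name] = sum_code(df[name].to_numpy())
        return coded[name]

    for fe in spec.fixed_effects:
        cols.append(factor(fe))
        names.append(fe)
    X = np.column_stack(cols)
    terms = [RandomTerm.intercept(g, df[g].to_numpy()) for g in spec.random_intercepts]
    terms += [
        RandomTerm.slope(f"{g}:{fac}", df[g].to_numpy(), factor(fac))
        for g, fac in spec.random_slopes
    ]
    return y, X, terms, names


# ---------------------------------------------------------------------------
# Laplace fitter


@dataclass
class GlmmFit:
    beta: np.ndarray
    se: np.ndarray
    sigma: dict[str, float]
    converged: bool
    singular: bool
    n_obs: int
    loglik: float
    term_names: list[str] = field(default_factory=list)
    reason: str = ""
    u: list[np.ndarray] = field(default_factory=list)

    def z(self, term: str | int = 0) -> float:
        i = term if isinstance(term, int) else self.term_names.index(term)
        return float(self.beta[i] / self.se[i])

    def coef(self, term: str) -> float:
        return float(self.beta[self.term_names.index(term)])


def _neg_bernoulli_ll(y, eta):
    # -(y*eta - log(1+e^eta)), numerically stable
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def _assemble(y, X, terms, sig2, beta, u, mu=None):
    """Gradient and Hessian blocks of the penalized log-likelihood."""
    n, p = X.shape
    eta = X @ beta
    for t, uk in zip(terms, u):
        eta = eta + t.values * uk[t.codes]
    mu = special.expit(eta)
    w = mu * (1.0 - mu) + 1e-12
    r = y - mu
    g_beta = X.T @ r
    g_u = [
        np.bincount(t.codes, weights=t.values * r, minlength=t.n_levels) - uk / s2
        for t, uk, s2 in zip(terms, u, sig2)
    ]
    # Hessian (negative curvature): [[A, B], [B^T, C + D^-1]]
    A = X.T @ (w[:, None] * X)
    B_blocks = []
    for t in terms:
        wb = w * t.values
        B_blocks.append(
            np.stack(
                [np.bincount(t.codes, weights=wb * X[:, j], minlength=t.n_levels) for j in range(p)]
            )
        )  # p x q_k
    K = len(terms)
    C_blocks = [[None] * K for _ in range(K)]
    for a in range(K):
        ta = terms[a]
        for b in range(a, K):
            tb = terms[b]
            flat = ta.codes * tb.n_levels + tb.codes
            blk = np.bincount(
                flat, weights=w * ta.values * tb.values, minlength=ta.n_levels * tb.n_levels
            ).reshape(ta.n_levels, tb.n_levels)
            C_blocks[a][b] = blk
            if a != b:
                C_blocks[b][a] = blk.T
    for a in range(K):
        C_blocks[a][a] = C_blocks[a][a] + np.diag(np.full(terms[a].n_levels, 1.0 / sig2[a]))
    return eta, g_beta, g_u, A, B_blocks, C_blocks


def _stack_H(A, B_blocks, C_blocks, terms):
    p = A.shape[0]
    q = sum(t.n_levels for t in terms)
    H = np.empty((p + q, p + q))
    H[:p, :p] = A
    off = p
    offs = []
    for t, B in zip(terms, B_blocks):
        H[:p, off : off + t.n_levels] = B
        H[off : off + t.n_levels, :p] = B.T
        offs.append(off)
        off += t.n_levels
    for a, ta in enumerate(terms):
        for b, tb in enumerate(terms):
            H[offs[a] : offs[a] + ta.n_levels, offs[b] : offs[b] + tb.n_levels] = C_blocks[a][b]
    return H


def _penalized_obj(y, X, terms, sig2, beta, u):
    eta = X @ beta
    for t, uk in zip(terms, u):
        eta = eta + t.values * uk[t.codes]
    pen = sum(0.5 * np.sum(uk**2) / s2 for uk, s2 in zip(u, sig2))
    return _neg_bernoulli_ll(y, eta) + pen


def _joint_mode(y, X, terms, sig2, beta0, u0, max_iter=60, tol=1e-7):
    """Newton iteration to the joint (beta, u) mode for fixed variances."""
    p = X.shape[1]
    beta = beta0.copy()
    u = [uk.copy() for uk in u0]
    obj = _penalized_obj(y, X, terms, sig2, beta, u)
    ok = True
    for _ in range(max_iter):
        _, g_beta, g_u, A, B, C = _assemble(y, X, terms, sig2, beta, u)
        g = np.concatenate([g_beta] + g_u) if terms else g_beta
        gnorm = np.max(np.abs(g)) if g.size else 0.0
        if gnorm < tol * max(1.0, len(y) / 100.0):
            break
        H = _stack_H(A, B, C, terms) if terms else A
        try:
            cf = linalg.cho_factor(H, lower=True, check_finite=False)
            step = linalg.cho_solve(cf, g, check_finite=False)
        except linalg.LinAlgError:
            ok = False
            break
        # step-halving line search on the penalized objective
        scale = 1.0
        for _ls in range(25):
            nb = beta + scale * step[:p]
            nu, off = [], p
            for t, uk in zip(terms, u):
                nu.append(uk + scale * step[off : off + t.n_levels])
                off += t.n_levels
            nobj = _penalized_obj(y, X, terms, sig2, nb, nu)
            if nobj <= obj + 1e-10:
                beta, u, obj = nb, nu, nobj
                break
            scale *= 0.5
        else:
            ok = False
            break
    else:
        ok = gnorm < 1e-3
    return beta, u, obj, ok


def _laplace_nll(y, X, terms, sig2, state):
    """Negative Laplace log marginal likelihood, warm-started via ``state``."""
    beta, u, obj, ok = _joint_mode(y, X, terms, sig2, state["beta"], state["u"])
    if not ok:
        return np.inf
    state["beta"], state["u"] = beta, u
    _, _, _, A, B, C = _assemble(y, X, terms, sig2, beta, u)
    # -ll = obj + 0.5 log det(H_uu) + 0.5 sum q_k log sig2_k
    val = obj
    if terms:
        q = sum(t.n_levels for t in terms)
        Huu = np.empty((q, q))
        offs, off = [], 0
        for t in terms:
            offs.append(off)
            off += t.n_levels
        for a, ta in enumerate(terms):
            for b, tb in enumerate(terms):
                Huu[offs[a] : offs[a] + ta.n_levels, offs[b] : offs[b] + tb.n_levels] = C[a][b]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return np.inf
        val += 0.5 * logdet + 0.5 * sum(t.n_levels * np.log(s2) for t, s2 in zip(terms, sig2))
    return val


def fit_logit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    terms: Sequence[RandomTerm] = (),
    *,
    term_names: Sequence[str] | None = None,
    fix_sigma: dict[str, float] | float | None = None,
    start_sigma: float | Sequence[float] = 0.5,
    start_beta: np.ndarray | None = None,
    start_u: Sequence[np.ndarray] | None = None,
    fast: bool = False,
) -> GlmmFit:
    """ML/Laplace fit of a binomial-logit model with independent random terms.

    ``fix_sigma`` pins random-effect SDs (scalar for all terms, or a mapping
    by term name); a fixed SD of 0 removes the term, so ``fix_sigma=0``
    reduces the fit to ordinary logistic regression (the oracle-equivalence
    contract used in tests).

    ``start_sigma``/``start_beta``/``start_u`` seed the optimization (e.g.
    from a pilot fit of comparable data); ``fast=True`` shrinks the
    variance-profiling budget accordingly.  Starting values and budget are
    part of the deterministic fitting procedure: repeated scans (as in
    permutation tests) apply identical settings to every dataset.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    names = list(term_names) if term_names is not None else [f"b{i}" for i in range(p)]
    terms = list(terms)

    def _fail(reason):
        return GlmmFit(
            beta=np.full(p, np.nan),
            se=np.full(p, np.nan),
            sigma={t.name: np.nan for t in terms},
            converged=False,
            singular=False,
            n_obs=n,
            loglik=np.nan,
            term_names=names,
            reason=reason,
        )

    if n == 0:
        return _fail("no observations")
    if y.min() == y.max():
        return _fail("no variation in response (complete separation)")

    # resolve fixed variances; sigma == 0 removes the term
    if fix_sigma is None:
        fixed = {}
    elif np.isscalar(fix_sigma):
        fixed = {t.name: float(fix_sigma) for t in terms}
    else:
        fixed = {k: float(v) for k, v in fix_sigma.items()}
    kept, kept_fixed = [], []
    for t in terms:
        s = fixed.get(t.name)
        if s is not None and s <= 0.0:
            continue
        kept.append(t)
        kept_fixed.append(s)
    free_idx = [i for i, s in enumerate(kept_fixed) if s is None]

    beta_init = np.zeros(p)
    if start_beta is not None and np.shape(start_beta) == (p,):
        beta_init = np.asarray(start_beta, float).copy()
    u_init = [np.zeros(t.n_levels) for t in kept]
    if start_u is not None and len(start_u) == len(kept) and all(
        len(uk) == t.n_levels for uk, t in zip(start_u, kept)
    ):
        u_init = [np.asarray(uk, float).copy() for uk in start_u]
    state = {"beta": beta_init, "u": u_init}

    def sig2_of(x):
        sig = np.empty(len(kept))
        for i, s in enumerate(kept_fixed):
            if s is not None:
                sig[i] = s
        for j, i in enumerate(free_idx):
            sig[i] = np.clip(np.exp(x[j]), 1e-8, 50.0)
        return sig**2

    if free_idx:
        ss = np.broadcast_to(np.atleast_1d(np.asarray(start_sigma, float)), (len(kept),))
        x0 = np.log(np.clip(ss[free_idx], 1e-4, 50.0))
        if fast:
            options = {"xatol": 0.06, "fatol": 5e-3, "maxfev": 50}
        else:
            options = {"xatol": 0.03, "fatol": 1e-3, "maxfev": 80 * max(1, len(free_idx))}
        res = optimize.minimize(
            lambda x: _laplace_nll(y, X, kept, sig2_of(x), state),
            x0,
            method="Nelder-Mead",
            options=options,
        )
        xbest = res.x
    else:
        xbest = np.empty(0)

    sig2 = sig2_of(xbest)
    beta, u, obj, ok = _joint_mode(y, X, kept, sig2, state["beta"], state["u"])
    if not ok:
        return _fail("inner Newton failed")
    eta, g_beta, g_u, A, B, C = _assemble(y, X, kept, sig2, beta, u)
    H = _stack_H(A, B, C, kept) if kept else A
    try:
        cf = linalg.cho_factor(H, lower=True, check_finite=False)
        rhs = np.zeros((p + sum(t.n_levels for t in kept), p))
        rhs[:p, :p] = np.eye(p)
        cov_beta = linalg.cho_solve(cf, rhs, check_finite=False)[:p, :p]
    except linalg.LinAlgError:
        return _fail("Hessian not positive definite")
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))

    sigma = {}
    for i, (t, s) in enumerate(zip(kept, kept_fixed)):
        sigma[t.name] = float(s) if s is not None else float(np.sqrt(sig2[i]))
    for t in terms:
        if t.name not in sigma:
            sigma[t.name] = 0.0

    if np.any(np.abs(beta) > _MAX_ABS_BETA) or np.any(~np.isfinite(se)) or np.any(se > _MAX_SE):
        fit = _fail("estimates diverged (separation or inestimable cell)")
        fit.beta, fit.se, fit.sigma = beta, se, sigma
        return fit

    loglik = -_laplace_nll(y, X, kept, sig2, state) if kept else -_neg_bernoulli_ll(y, X @ beta)
    singular = any(v < _SINGULAR_SD for k, v in sigma.items())
    return GlmmFit(
        beta=beta,
        se=se,
        sigma=sigma,
        converged=True,
        singular=singular,
        n_obs=n,
        loglik=float(loglik),
        term_names=names,
        u=u,
    )


# ---------------------------------------------------------------------------
# per-bin wrappers


@dataclass
class BinModelResult:
    """Per-bin focal estimate with the carry-forward bookkeeping."""

    bin: int
    estimate: float
    se: float
    z: float
    converged: bool
    singular: bool = False
    carried: bool = False
    n_obs: int = 0
    reason: str = ""


def fit_bin_model(df: pd.DataFrame, spec: BinModelSpec, **kwargs) -> GlmmFit:
    """Fit the specified model to one bin's rows (response must be non-missing)."""
    df = df.loc[df[spec.response].notna()]
    if df.empty:
        fit = fit_logit_glmm(np.empty(0), np.empty((0, 1)))
        fit.reason = "no observations"
        return fit
    if df["subject"].nunique() < 2:
        fit = fit_logit_glmm(np.empty(0), np.empty((0, 1)))
        fit.reason = "fewer than 2 subjects"
        return fit
    y, X, terms, names = build_design(df, spec)
    return fit_logit_glmm(y, X, terms, term_names=names, **kwargs)


def scan_window(
    binned: pd.DataFrame,
    spec: BinModelSpec,
    bins: Sequence[int] | None = None,
    **kwargs,
) -> list[BinModelResult]:
    """Fit the bin model at every bin, applying the fallback conventions.

    A bin whose model does not converge (or cannot be fit) inherits the
    estimate, SE and z used at the previous bin; at the first bin the
    estimate and z are set to zero.  Inherited bins are flagged ``carried``.
    """
    if bins is None:
        bins = sorted(binned["bin"].unique())
    bins = list(bins)
    if not bins:
        raise ValueError("empty analysis window")
    focal = 0 if spec.focal == "intercept" else (1 + list(spec.fixed_effects).index(spec.focal))
    results: list[BinModelResult] = []
    prev = (0.0, np.nan, 0.0)
    grouped = {b: g for b, g in binned.groupby("bin", sort=True)}
    for b in bins:
        sub = grouped.get(b)
        fit = fit_bin_model(sub, spec, **kwargs) if sub is not None else None
        if fit is not None and fit.converged:
            est, se = float(fit.beta[focal]), float(fit.se[focal])
            z = est / se if se > 0 else 0.0
            results.append(
                BinModelResult(b, est, se, z, True, fit.singular, False, fit.n_obs)
            )
            prev = (est, se, z)
        else:
            reason = fit.reason if fit is not None else "no data for bin"
            est, se, z = prev
            results.append(
                BinModelResult(
                    b, est, se, z, False, False, True,
                    fit.n_obs if fit is not None else 0, reason,
                )
            )
    return results


# ---------------------------------------------------------------------------
# exact oracle (tests only)


def fit_exact_single_grouping(
    y: np.ndarray,
    X: np.ndarray,
    groups: Sequence,
    sigma_grid: Sequence[float],
    gh_points: int = 31,
):
    """Exact ML fit (Gauss-Hermite) for one random intercept, profiled on a grid.

    Independent oracle for tiny datasets: the random-intercept likelihood is
    integrated exactly per group and the SD is profiled over ``sigma_grid``.
    Returns (best_sigma, best_beta, best_loglik).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    codes, _ = pd.factorize(np.asarray(groups), sort=True)
    nodes, weights = np.polynomial.hermite.hermgauss(gh_points)
    logw = np.log(weights / np.sqrt(np.pi))

    def nll(beta, sigma):
        eta0 = X @ beta
        total = 0.0
        for g in range(codes.max() + 1):
            m = codes == g
            # n_g x gh matrix of per-node log-likelihood contributions
            eta = eta0[m][:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
            ll = y[m][:, None] * eta - np.logaddexp(0.0, eta)
            total += special.logsumexp(ll.sum(axis=0) + logw)
        return -total

    best = (None, None, -np.inf)
    p = X.shape[1]
    for sigma in sigma_grid:
        res = optimize.minimize(lambda b: nll(b, sigma), np.zeros(p), method="BFGS")
        if -res.fun > best[2]:
            best = (sigma, res.x, -res.fun)
    return best
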