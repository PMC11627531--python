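"""Binomial mixed-model fitter: oracles, fallback rules, invariances."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from gazepipe.glmm import (
    BinModelSpec,
    RandomTerm,
    build_design,
    fit_bin_model,
    fit_exact_single_grouping,
    fit_logit_glmm,
    scan_window,
    sum_code,
)


def _crossed_data(n_subj=20, n_item=10, beta0=-0.4, beta_c=0.4, sd_s=0.8, sd_i=0.4, seed=0):
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_subj), n_item * 2)
    item = np.tile(np.repeat(np.arange(n_item), 2), n_subj)
    cond = np.tile([1.0, -1.0], n_subj * n_item)
    u = rng.normal(0, sd_s, n_subj)
    w = rng.normal(0, sd_i, n_item)
    eta = beta0 + beta_c * cond + u[subj] + w[item]
    y = (rng.random(len(eta)) < expit(eta)).astype(float)
    X = np.column_stack([np.ones(len(y)), cond])
    terms = [RandomTerm.intercept("subject", subj), RandomTerm.intercept("item", item)]
    return y, X, terms, subj, item, cond


class TestOracles:
    def test_zero_variance_matches_plain_logistic(self):
        """With variance components at 0 the fit equals ordinary logistic
        regression to <= 1e-4 on the logit scale."""
        y, X, terms, *_ = _crossed_data(seed=1)
        ours = fit_logit_glmm(y, X, terms, fix_sigma=0.0)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.abs(ours.beta - glm.params).max() < 1e-4
        assert np.abs(ours.se - glm.bse).max() < 1e-4

    def test_homogeneous_subjects_collapse_to_pooled_logit(self):
        """All subjects at 60% success: intercept ~ ln(0.6/0.4), variance ~ 0
        (singular but converged)."""
        y = np.tile([1.0] * 6 + [0.0] * 4, 10)
        subj = np.repeat(np.arange(10), 10)
        fit = fit_logit_glmm(
            y, np.ones((100, 1)), [RandomTerm.intercept("subject", subj)]
        )
        assert fit.converged and fit.singular
        assert fit.beta[0] == pytest.approx(np.log(0.6 / 0.4), abs=1e-3)

    def test_gauss_hermite_exact_oracle(self):
        """Laplace fit agrees with exact (quadrature) ML on one grouping factor."""
        rng = np.random.default_rng(4)
        subj = np.repeat(np.arange(12), 30)
        u = rng.normal(0, 0.8, 12)
        y = (rng.random(len(subj)) < expit(-0.3 + u[subj])).astype(float)
        X = np.ones((len(y), 1))
        sig_exact, beta_exact, _ = fit_exact_single_grouping(
            y, X, subj, sigma_grid=np.linspace(0.05, 1.6, 32)
        )
        ours = fit_logit_glmm(y, X, [RandomTerm.intercept("subject", subj)])
        assert ours.beta[0] == pytest.approx(beta_exact[0], abs=0.05)
        assert ours.sigma["subject"] == pytest.approx(sig_exact, abs=0.1)

    def test_matches_lme4_glmer(self, tmp_path):
        """Cross-check against lme4's Laplace fit on crossed random intercepts."""
        y, X, terms, subj, item, cond = _crossed_data(n_subj=15, n_item=8, seed=12)
        df = pd.DataFrame(dict(y=y, cond=cond, subj=subj, item=item))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            m <- glmer(y ~ cond + (1|subj) + (1|item), data=d, family=binomial)
            cat(fixef(m)[1], fixef(m)[2], sqrt(diag(vcov(m))))
        """)
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        b0, b1, se0, se1 = map(float, out.stdout.split()[:4])
        ours = fit_logit_glmm(y, X, terms)
        assert ours.beta[0] == pytest.approx(b0, abs=0.03)
        assert ours.beta[1] == pytest.approx(b1, abs=0.03)
        assert ours.se[0] == pytest.approx(se0, abs=0.01)
        assert ours.se[1] == pytest.approx(se1, abs=0.01)

    def test_recovers_generating_effect(self):
        """Sum-coded condition effect beta = 0.8 at n = 40 subjects is
        recovered within 3 SE."""
        y, X, terms, *_ = _crossed_data(n_subj=40, n_item=12, beta_c=0.8, sd_s=1.0, seed=5)
        fit = fit_logit_glmm(y, X, terms)
        assert fit.converged
        assert abs(fit.beta[1] - 0.8) < 3 * fit.se[1]


class TestDegenerate:
    def test_constant_response_is_separation(self):
        fit = fit_logit_glmm(np.ones(50), np.ones((50, 1)),
                             [RandomTerm.intercept("s", np.repeat(np.arange(5), 10))])
        assert not fit.converged and "separation" in fit.reason

    def test_fewer_than_two_subjects_rejected(self):
        df = pd.DataFrame(dict(subject=0, item=[0, 1] * 5, competitor_quad=[0.0, 1.0] * 5,
                               condition=["a", "b"] * 5))
        spec = BinModelSpec(response="competitor_quad", fixed_effects=("condition",),
                            focal="condition")
        fit = fit_bin_model(df, spec)
        assert not fit.converged and "subjects" in fit.reason


class TestSumCoding:
    def test_plus_one_for_first_sorted_level(self):
        assert sum_code(["b", "a", "a"]).tolist() == [-1.0, 1.0, 1.0]

    def test_three_levels_rejected(self):
        with pytest.raises(ValueError):
            sum_code(["a", "b", "c"])

    def test_z_sign_flips_under_relabeling(self):
        """Relabeling the sum-coded levels flips the sign of z only."""
        y, X, terms, subj, item, cond = _crossed_data(seed=8)
        fit_a = fit_logit_glmm(y, X, terms)
        X2 = X.copy()
        X2[:, 1] = -X2[:, 1]
        fit_b = fit_logit_glmm(y, X2, terms)
        assert fit_a.z(1) == pytest.approx(-fit_b.z(1), abs=0.02)


class TestScanWindow:
    def _binned(self, z_targets):
        """Construct a binned table; bins listed in ``z_targets`` as None get a
        constant response (inestimable -> fallback)."""
        rng = np.random.default_rng(0)
        rows = []
        for b, kind in enumerate(z_targets):
            for s in range(8):
                for t in range(10):
                    if kind is None:
                        y = 1.0
                    else:
                        y = float(rng.random() < 0.5 + kind)
                    rows.append(dict(subject=s, item=t % 4, trial=t, bin=b,
                                     condition=["a", "b"][t % 2], resp=y))
        return pd.DataFrame(rows)

    def test_all_converged_equals_per_bin_fits(self):
        binned = self._binned([0.0, 0.1, 0.0])
        spec = BinModelSpec(response="resp", fixed_effects=(), focal="intercept")
        res = scan_window(binned, spec)
        assert [r.carried for r in res] == [False, False, False]
        for r in res:
            fit = fit_bin_model(binned[binned["bin"] == r.bin], spec)
            assert r.estimate == pytest.approx(fit.beta[0], abs=1e-6)

    def test_failed_bin_carries_previous_estimates(self):
        binned = self._binned([0.2, None, 0.0])
        spec = BinModelSpec(response="resp", fixed_effects=(), focal="intercept")
        res = scan_window(binned, spec)
        assert res[1].carried and not res[0].carried
        assert res[1].z == res[0].z and res[1].estimate == res[0].estimate

    def test_failed_first_bin_reports_zero(self):
        binned = self._binned([None, 0.2])
        spec = BinModelSpec(response="resp", fixed_effects=(), focal="intercept")
        res = scan_window(binned, spec)
        assert res[0].carried and res[0].z == 0.0 and res[0].estimate == 0.0

    def test_empty_window_rejected(self):
        spec = BinModelSpec(response="resp", fixed_effects=(), focal="intercept")
        with pytest.raises(ValueError):
            scan_window(self._binned([0.0]), spec, bins=[])


def test_build_design_interaction_column():
    df = pd.DataFrame(dict(
        resp=[0.0, 1.0, 1.0, 0.0], condition=["a", "a", "b", "b"],
        method=["m1", "m2", "m1", "m2"], subject=[0, 0, 1, 1], item=[0, 1, 0, 1],
    ))
    spec = BinModelSpec(response="resp",
                        fixed_effects=("condition", "method", "condition:method"),
                        focal="condition:method")
    y, X, terms, names = build_design(df, spec)
    assert names == ["intercept", "condition", "method", "condition:method"]
    assert np.array_equal(X[:, 3], X[:, 1] * X[:, 2])
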