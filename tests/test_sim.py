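"""Synthetic gaze generator: determinism, noise calibration, channel fidelity."""

import numpy as np
import pandas as pd
import pytest

from gazepipe.preprocess import CENTER, OFF_OR_UNKNOWN, bin_looks
from gazepipe.sim import (
    ConditionEffect,
    EffectSpec,
    MethodModel,
    cohort_effects,
    render_coordinates,
    render_labels,
    sample_timeline,
    simulate_binned_looks,
    simulate_experiment,
    task_design,
)


def _noise_free_spec(base=300.0):
    return EffectSpec(base_latency_ms=base, latency_sd_ms=0, subject_sd_ms=0, item_sd_ms=0)


class TestTimeline:
    def test_noise_free_switch_at_base_latency(self, rng):
        design = task_design("fixation")
        tl = sample_timeline(design, _noise_free_spec(300.0), 0, 0, None, rng)
        # center until alignment zero + 300 ms, target afterwards
        assert tl.intervals[0][2] == CENTER
        assert tl.intervals[0][1] == design.align_zero_ms + 300
        assert tl.intervals[-1][2] == "top_left"

    def test_forced_competitor_interval_inside_window(self, rng):
        design = task_design("phonemic_cohort")
        spec = EffectSpec(
            base_latency_ms=250, latency_sd_ms=0, subject_sd_ms=0, item_sd_ms=0,
            condition_effects={"cohort": ConditionEffect(
                competitor_prob=1.0, competitor_window=(400, 900), competitor_dwell_ms=300)},
        )
        for _ in range(20):
            tl = sample_timeline(design, spec, 0, 0, "cohort", rng,
                                 target_roi="top_left", competitor_roi="bottom_right")
            comp = [iv for iv in tl.intervals if iv[2] == "bottom_right"]
            assert len(comp) == 1
            s, e, _ = comp[0]
            assert design.align_zero_ms + 400 <= s and e <= design.align_zero_ms + 900

    def test_latency_distribution_mean(self, rng):
        design = task_design("fixation")
        spec = EffectSpec(base_latency_ms=300, latency_sd_ms=50, subject_sd_ms=0, item_sd_ms=0)
        lat = [
            sample_timeline(design, spec, 0, 0, None, rng).latency_ms for _ in range(10_000)
        ]
        se = 50 / np.sqrt(10_000)
        assert abs(np.mean(lat) - 300) < 3 * se

    def test_latency_floor(self, rng):
        design = task_design("fixation")
        spec = EffectSpec(base_latency_ms=90, latency_sd_ms=80, subject_sd_ms=0, item_sd_ms=0)
        lat = [sample_timeline(design, spec, 0, 0, None, rng).latency_ms for _ in range(500)]
        assert min(lat) >= 80.0

    def test_effect_window_outside_trial_rejected(self, rng):
        design = task_design("phonemic_cohort")
        spec = EffectSpec(condition_effects={"cohort": ConditionEffect(
            competitor_prob=1.0, competitor_window=(400, 99_000))})
        with pytest.raises(ValueError, match="outside the trial"):
            sample_timeline(design, spec, 0, 0, "cohort", rng, competitor_roi="top_right")


class TestRender:
    def test_noise_free_samples_on_centroids(self, rng):
        design = task_design("fixation")
        tl = sample_timeline(design, _noise_free_spec(), 0, 0, None, rng)
        m = MethodModel("clean", fps=60)
        f = render_coordinates(tl, m, rng)
        on_center = f["time_ms"] < design.align_zero_ms + 300
        assert np.allclose(f.loc[on_center, ["x", "y"]], 0.5)
        assert np.allclose(f.loc[~on_center, ["x", "y"]], 0.25)

    def test_latency_delays_rendered_switch(self, rng):
        design = task_design("fixation")
        tl = sample_timeline(design, _noise_free_spec(300.0), 0, 0, None, rng)
        lagged = render_coordinates(tl, MethodModel("lag", fps=100, latency_ms=300), rng)
        onset = lagged.loc[lagged["x"] < 0.4, "time_ms"].min()
        assert onset == pytest.approx(design.align_zero_ms + 600, abs=11)

    def test_rayleigh_mean_offset(self, rng):
        """Per-axis Gaussian sd 0.05 gives mean offset 0.05*sqrt(pi/2)."""
        design = task_design("fixation")
        tl = sample_timeline(design, _noise_free_spec(), 0, 0, None, rng)
        m = MethodModel("noisy", fps=100, spatial_sd=0.05)
        offs = []
        for _ in range(80):
            f = render_coordinates(tl, m, rng)
            f = f[f["time_ms"] < design.align_zero_ms]  # fixed centroid (0.5, 0.5)
            offs.append(np.hypot(f["x"] - 0.5, f["y"] - 0.5))
        mean_off = float(np.concatenate(offs).mean())
        assert mean_off == pytest.approx(0.05 * np.sqrt(np.pi / 2), rel=0.05)

    def test_label_stream_matches_lagged_truth(self, rng):
        design = task_design("fixation")
        tl = sample_timeline(design, _noise_free_spec(300.0), 0, 0, None, rng)
        m = MethodModel("ann", fps=25, output_mode="labels", latency_ms=200)
        f = render_labels(tl, m, rng)
        expected = tl.roi_at(np.clip(f["time_ms"] - 200, 0, design.trial_duration_ms - 1))
        assert (f["label"].to_numpy() == expected).all()

    def test_full_trackloss_labels_offscreen(self, rng):
        design = task_design("fixation")
        tl = sample_timeline(design, _noise_free_spec(), 0, 0, None, rng)
        m = MethodModel("lost", fps=25, output_mode="labels", trackloss_rate=1.0)
        f = render_labels(tl, m, rng)
        assert (f["label"] == OFF_OR_UNKNOWN).all()

    def test_label_error_rate_calibrated(self, rng):
        design = task_design("fixation")
        tl = sample_timeline(design, _noise_free_spec(), 0, 0, None, rng)
        m = MethodModel("err", fps=1000, output_mode="labels", label_error_rate=0.1)
        f = render_labels(tl, m, rng)
        truth = tl.roi_at(f["time_ms"].to_numpy())
        frac = np.mean(f["label"].to_numpy() != truth)
        n = len(f)
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)


class TestExperiment:
    def test_same_seed_identical_datasets(self):
        design = task_design("fixation")
        kw = dict(n_subjects=3, n_items=4, design=design, effects=EffectSpec(),
                  methods=[MethodModel("a", fps=30, spatial_sd=0.05)], seed=11)
        r1, r2 = simulate_experiment(**kw), simulate_experiment(**kw)
        pd.testing.assert_frame_equal(r1.datasets["a"], r2.datasets["a"])
        pd.testing.assert_frame_equal(r1.design_table, r2.design_table)

    def test_shared_latent_behavior_across_channels(self):
        """Two channels with identical parameters see the same latent truth."""
        design = task_design("fixation")
        ms = [MethodModel("a", fps=30), MethodModel("b", fps=30)]
        r = simulate_experiment(2, 4, design, _noise_free_spec(), ms, seed=5)
        # noise-free channels at the same fps render identical positions
        a = r.datasets["a"][["subject", "trial", "time_ms", "x", "y"]]
        b = r.datasets["b"][["subject", "trial", "time_ms", "x", "y"]]
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_trial_loss_rate(self):
        design = task_design("fixation", trial_count=100)
        m = MethodModel("lossy", fps=10, trial_loss_rate=0.5)
        r = simulate_experiment(10, 4, design, _noise_free_spec(), [m], seed=13)
        lost = len(r.truth["lost_trials"]["lossy"])
        n = 10 * 100
        assert abs(lost / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_empty_method_list_rejected(self):
        with pytest.raises(ValueError, match="empty method list"):
            simulate_experiment(2, 2, task_design("fixation"), EffectSpec(), [], seed=0)

    def test_noise_free_roundtrip_recovers_latent_bins(self):
        """Channel fidelity: zero-noise rendering reproduces latent ROI bins."""
        design = task_design("fixation")
        m = MethodModel("clean", fps=50)
        r = simulate_experiment(2, 4, design, _noise_free_spec(300.0), [m], seed=21)
        binned = bin_looks(r.datasets["clean"], (0, 1500))
        for (s, t), grp in binned.groupby(["subject", "trial"]):
            target = r.design_table.query("subject == @s and trial == @t")["target_roi"].iloc[0]
            # latent switch at exactly 300 ms: bins 3+ are pure target fixation
            assert (grp.loc[grp["bin"] >= 3, target] == 1.0).all()
            assert (grp.loc[grp["bin"] < 3, "center"] == 1.0).all()


class TestBinnedGenerator:
    def test_effect_confined_to_window(self):
        df = simulate_binned_looks(
            60, 12, 10, effect_window_bins=(3, 7), effect_logit=0.8,
            baseline_logit=-1.0, subject_sd=0.3, item_sd=0.2, seed=7,
        )
        gap = (
            df.groupby(["bin", "condition"])["look"].mean().unstack("condition")
            .eval("cohort - control")
        )
        n = 60 * 12  # trials per condition per bin
        mc_se = np.sqrt(2 * 0.25 / n)
        assert (gap[3:7] > 2 * mc_se).all()
        outside = gap[[0, 1, 2, 7, 8, 9]]
        assert (outside.abs() < 3 * mc_se).all()

    def test_determinism(self):
        a = simulate_binned_looks(5, 4, 6, seed=3)
        b = simulate_binned_looks(5, 4, 6, seed=3)
        pd.testing.assert_frame_equal(a, b)
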