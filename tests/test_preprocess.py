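"""ROI assignment, binning/binarization, exclusion, and agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazepipe.preprocess import (
    CENTER,
    OFF_OR_UNKNOWN,
    QUADRANTS,
    RoiGeometry,
    annotation_agreement,
    assign_roi,
    bin_looks,
    exclude_trials,
    apply_exclusions,
    normalize_coordinates,
)


class TestNormalize:
    def test_screen_center_maps_to_half_half(self):
        assert normalize_coordinates(960, 540, 1920, 1080)[:2] == (0.5, 0.5)

    def test_corners(self):
        assert normalize_coordinates(0, 0, 1920, 1080)[:2] == (0.0, 0.0)
        x, y, valid = normalize_coordinates(1920, 1080, 1920, 1080)
        assert (x, y, valid) == (1.0, 1.0, True)

    def test_out_of_screen_flagged_invalid(self):
        x, y, valid = normalize_coordinates(2000, 500, 1920, 1080)
        assert not valid and x > 1

    def test_bad_dimensions_raise(self):
        with pytest.raises(ValueError):
            normalize_coordinates(1, 1, 0, 1080)


class TestAssignRoi:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            (0.5, 0.5, CENTER),
            (0.2, 0.2, "top_left"),
            (0.6, 0.4, "top_right"),
            (0.2, 0.8, "bottom_left"),
            (0.9, 0.9, "bottom_right"),
            # 16:9 geometry: center half-extents are 0.0422 in x, 0.075 in y
            (0.54, 0.52, CENTER),
            (0.55, 0.5, "top_right"),
        ],
    )
    def test_examples(self, x, y, expected):
        assert assign_roi(x, y, geom=RoiGeometry(aspect_ratio=16 / 9)) == expected

    def test_invalid_sample_is_offscreen(self):
        assert assign_roi(np.nan, 0.5) == OFF_OR_UNKNOWN
        assert assign_roi(0.5, 0.5, valid=False) == OFF_OR_UNKNOWN

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0.05, 0.5), st.floats(0.5, 3))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, x, y, cf, ar):
        """Every valid sample maps to exactly one of center + 4 quadrants."""
        label = assign_roi(x, y, geom=RoiGeometry(cf, ar))
        assert label in (CENTER,) + QUADRANTS


def _coord_trial(times, xs, ys, valid=None, **ids):
    n = len(times)
    base = dict(subject=0, trial=0)
    base.update(ids)
    return pd.DataFrame(
        {**{k: [v] * n for k, v in base.items()},
         "time_ms": times, "x": xs, "y": ys,
         "valid": valid if valid is not None else [True] * n}
    )


class TestBinLooks:
    def test_thirty_percent_threshold_inclusive(self):
        # 10 samples in one bin, 3 on the top-left quadrant -> indicator 1
        df = _coord_trial(
            np.arange(10) * 10.0,
            [0.2] * 3 + [0.75] * 7,
            [0.2] * 3 + [0.75] * 7,
        )
        b = bin_looks(df, (0, 100))
        assert b.loc[0, "top_left"] == 1.0
        assert b.loc[0, "bottom_right"] == 1.0

    def test_below_threshold_is_zero(self):
        df = _coord_trial(np.arange(10) * 10.0, [0.2] * 2 + [0.75] * 8, [0.2] * 2 + [0.75] * 8)
        b = bin_looks(df, (0, 100))
        assert b.loc[0, "top_left"] == 0.0

    def test_side_fifty_percent_threshold(self):
        # 5 samples: 3 on left quadrants (60%) -> left 1; 2/5 (40%) -> right 0
        df = _coord_trial(np.arange(5) * 20.0, [0.2, 0.2, 0.2, 0.8, 0.8], [0.2] * 5)
        b = bin_looks(df, (0, 100))
        assert b.loc[0, "left"] == 1.0 and b.loc[0, "right"] == 0.0

    def test_empty_bins_missing(self):
        df = _coord_trial([10.0], [0.2], [0.2])
        b = bin_looks(df, (0, 300))
        assert b.loc[0, "top_left"] == 1.0
        assert b.loc[1:, "top_left"].isna().all()
        assert (b.loc[1:, "missing"]).all()

    def test_invalid_samples_dilute_denominator(self):
        # 10 samples, 3 valid on top-left, 7 invalid: 30% of recorded -> 1
        df = _coord_trial(
            np.arange(10) * 10.0, [0.2] * 3 + [np.nan] * 7, [0.2] * 3 + [np.nan] * 7,
            valid=[True] * 3 + [False] * 7,
        )
        assert bin_looks(df, (0, 100)).loc[0, "top_left"] == 1.0
        # with valid-only denominators the same bin is 3/3 = 100%
        assert bin_looks(df, (0, 100), valid_only=True).loc[0, "top_left"] == 1.0

    def test_label_stream_equivalent(self):
        df = pd.DataFrame(
            dict(subject=0, trial=0, time_ms=np.arange(10) * 10.0,
                 label=["top_left"] * 3 + ["bottom_right"] * 7)
        )
        b = bin_looks(df, (0, 100))
        assert b.loc[0, "top_left"] == 1.0
        assert b.loc[0, "right"] == 1.0 and b.loc[0, "left"] == 0.0

    def test_window_must_align_to_grid(self):
        with pytest.raises(ValueError):
            bin_looks(_coord_trial([0.0], [0.5], [0.5]), (0, 150))

    @given(st.integers(1, 9))
    @settings(max_examples=20, deadline=None)
    def test_threshold_monotonicity(self, k):
        """Raising the ROI threshold never turns a 0 indicator into a 1."""
        df = _coord_trial(np.arange(10) * 10.0, [0.2] * k + [0.8] * (10 - k), [0.2] * 10)
        lo = bin_looks(df, (0, 100), roi_threshold=0.2)
        hi = bin_looks(df, (0, 100), roi_threshold=0.6)
        for q in QUADRANTS:
            assert hi.loc[0, q] <= lo.loc[0, q]

    def test_rate_invariance(self):
        """Identical per-bin proportions at different fps give identical bins."""
        fast = _coord_trial(np.arange(20) * 5.0, [0.2] * 10 + [0.8] * 10, [0.2] * 20)
        slow = _coord_trial(np.arange(4) * 25.0, [0.2] * 2 + [0.8] * 2, [0.2] * 4)
        cols = list(QUADRANTS) + ["left", "right", "center"]
        pd.testing.assert_frame_equal(
            bin_looks(fast, (0, 100))[cols], bin_looks(slow, (0, 100))[cols]
        )


class TestExclusion:
    def _ann(self, n_off, n_total, subject=0, trial=0):
        labels = [OFF_OR_UNKNOWN] * n_off + [CENTER] * (n_total - n_off)
        return pd.DataFrame(
            dict(subject=subject, trial=trial, time_ms=np.arange(n_total) * 40.0, label=labels)
        )

    def test_strictly_more_than_half_excluded(self):
        res = exclude_trials(self._ann(51, 100))
        assert res.loc[0, "excluded"]

    def test_exactly_half_kept(self):
        res = exclude_trials(self._ann(50, 100))
        assert not res.loc[0, "excluded"]

    def test_all_center_kept(self):
        assert not exclude_trials(self._ann(0, 100)).loc[0, "excluded"]

    def test_exclusion_propagates_to_other_methods(self):
        ann = pd.concat([self._ann(60, 100, trial=0), self._ann(0, 100, trial=1)])
        res = exclude_trials(ann)
        coord = pd.DataFrame(
            dict(subject=0, trial=[0, 1], time_ms=0.0, x=0.5, y=0.5, valid=True)
        )
        kept = apply_exclusions(coord, res)
        assert kept["trial"].tolist() == [1]


class TestAgreement:
    def test_identical_streams(self):
        assert annotation_agreement(["a"] * 10, ["a"] * 10) == 100.0

    def test_nine_of_ten(self):
        assert annotation_agreement(["a"] * 9 + ["b"], ["a"] * 10) == 90.0

    def test_random_uniform_labels_near_one_sixth(self, rng):
        labels = np.array(list("abcdef"))
        a = rng.choice(labels, 10_000)
        b = rng.choice(labels, 10_000)
        agree = annotation_agreement(a, b)
        se = 100 * np.sqrt((1 / 6) * (5 / 6) / 10_000)
        assert abs(agree - 100 / 6) < 3 * se

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            annotation_agreement(["a"], ["a", "b"])
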