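"""Bin and binarize the raw channels; apply the attention exclusion rule.

Reads the raw sample tables from 01, assigns each sample to an ROI
(center square = 15% of screen height; quadrants minus the overlap), bins
looks into 100 ms windows (ROI indicators at the 30% threshold, screen
sides at 50%), excludes trials whose annotation stream is >50% off-screen
(propagating the exclusion to the co-recorded channels), and attaches the
design-derived responses (target/competitor quadrant looks, target-side
looks).  Writes one binned table per task x channel.
"""

import argparse
from pathlib import Path

import pandas as pd

from gazepipe.pipeline import add_design_responses
from gazepipe.preprocess import apply_exclusions, bin_looks, exclude_trials

WINDOWS = {"fixation": (0, 1500), "phonemic_cohort": (0, 1500)}
CHANNELS = ("infrared", "manual", "webgazer")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data_dir = args.out / "data"

    for task, window in WINDOWS.items():
        design = pd.read_csv(data_dir / f"{task}_design.csv")
        ann = pd.read_csv(data_dir / f"{task}_manual.csv")
        exclusions = exclude_trials(ann, id_cols=["subject", "trial"])
        n_excl = int(exclusions["excluded"].sum())
        print(f"{task}: {n_excl} trial(s) excluded for inattention "
              f"(> 50% off-screen in the annotation stream)")
        for name in CHANNELS:
            raw = pd.read_csv(data_dir / f"{task}_{name}.csv")
            raw = apply_exclusions(raw, exclusions)
            binned = bin_looks(raw, window)
            binned = add_design_responses(binned, design)
            path = data_dir / f"{task}_{name}_binned.csv"
            binned.to_csv(path, index=False)
            miss = binned["missing"].mean()
            print(f"  {name}: {len(binned)} trial-bins, {miss:.1%} empty -> {path}")


if __name__ == "__main__":
    main()
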