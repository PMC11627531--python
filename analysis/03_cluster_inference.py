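"""Cluster-mass permutation inference per task and channel.

Fixation task: per channel, tests when target-side looks exceed 50% chance
on the horizontal and vertical axes (intercept-only per-bin models,
target-side reshuffle permutations).  Phonemic cohort task: per channel,
tests when competitor-quadrant looks differ between the cohort and control
conditions (sum-coded condition effect, condition labels permuted within
subjects).  Writes all clusters with z-sums and permutation p-values.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gazepipe.cluster import cluster_permutation_test
from gazepipe.glmm import BinModelSpec
from gazepipe.pipeline import _jsonable, run_chance_analysis

CHANNELS = ("infrared", "manual", "webgazer")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--nperm", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data_dir = args.out / "data"
    report = {}

    print("== fixation: target-side looks vs 50% chance ==")
    for name in CHANNELS:
        b = pd.read_csv(data_dir / f"fixation_{name}_binned.csv")
        results, es = run_chance_analysis(b, n_perm=args.nperm, seed=args.seed)
        report[f"fixation_{name}"] = {
            ax: r.summary().to_dict(orient="records") for ax, r in results.items()
        }
        for ax, r in results.items():
            for c in r.significant_clusters():
                lo, hi = c.span_ms()
                print(f"  {name} {ax}: {'above' if c.sign > 0 else 'below'} chance "
                      f"{lo}-{hi} ms, z-sum = {c.z_sum:.2f}, p {c.p_str}")

    print("== phonemic cohort: condition effect on competitor looks ==")
    spec = BinModelSpec(response="competitor_quad", fixed_effects=("condition",),
                        focal="condition")
    for name in CHANNELS:
        b = pd.read_csv(data_dir / f"phonemic_cohort_{name}_binned.csv")
        res = cluster_permutation_test(b, spec, "condition_within_subject",
                                       n_perm=args.nperm, seed=args.seed)
        report[f"cohort_{name}"] = res.summary().to_dict(orient="records")
        sig = res.significant_clusters()
        if sig:
            for c in sig:
                lo, hi = c.span_ms()
                print(f"  {name}: cohort effect {lo}-{hi} ms, "
                      f"z-sum = {c.z_sum:.2f}, p {c.p_str}")
        else:
            print(f"  {name}: no significant cluster")

    out_path = args.out / "clusters.json"
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main()
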