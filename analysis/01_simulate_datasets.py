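"""Simulate the study's task battery through three recording channels.

Generates synthetic multi-method gaze data for the fixation and phonemic
cohort tasks (the two analysis archetypes: chance-level side looks and a
condition effect) plus the smooth-pursuit stimulus trajectory, using the
default channel models (60 fps precise coordinates, 25 fps annotation
labels, 26 fps noisy lagged coordinates).  Writes one raw sample table per
task x channel plus the trial design and ground truth under results/data/.
"""

import argparse
import json
from pathlib import Path

from gazepipe.pipeline import _jsonable
from gazepipe.sim import (
    EffectSpec,
    cohort_effects,
    default_methods,
    simulate_experiment,
    task_design,
)
from gazepipe.pursuit import make_trajectory

N_SUBJECTS = 16
N_ITEMS_COHORT = 18


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data_dir = args.out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)

    tasks = {
        "fixation": (task_design("fixation"), EffectSpec(stray_rate_hz=0.15), 4),
        "phonemic_cohort": (
            task_design("phonemic_cohort"),
            cohort_effects(excess=0.15, base_prob=0.08, window=(400.0, 900.0)),
            N_ITEMS_COHORT,
        ),
    }
    for task, (design, effects, n_items) in tasks.items():
        sim = simulate_experiment(N_SUBJECTS, n_items, design, effects,
                                  default_methods(), seed=args.seed)
        for name, ds in sim.datasets.items():
            path = data_dir / f"{task}_{name}.csv"
            ds.to_csv(path, index=False)
            print(f"{task}/{name}: {len(ds)} samples, "
                  f"{ds.groupby(['subject', 'trial']).ngroups} trials -> {path}")
        sim.design_table.to_csv(data_dir / f"{task}_design.csv", index=False)
        with open(data_dir / f"{task}_truth.json", "w") as fh:
            json.dump(sim.truth, fh, indent=2, default=_jsonable)

    track = make_trajectory(rect=(0.2, 0.2, 0.8, 0.8), speed=0.25,
                            duration_ms=45_000, seed=args.seed)
    track.to_frame().to_csv(data_dir / "pursuit_track.csv", index=False)
    print(f"pursuit track: {len(track.times_ms)} samples over 45 s")


if __name__ == "__main__":
    main()
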