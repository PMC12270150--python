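#!/usr/bin/env python
"""Simulate the study's plate runs and write them as canonical CSVs.

Generates the two packaged scenarios — the Ni/LPS ±CV-inhibition
dose-response (mito stress test, 4 experiments) and the ATP-budget fixture
(mito + glyco stress tests, 3 experiments) — and writes one cycles/wells
CSV pair per plate plus a ground-truth JSON per scenario under
results/sim/.  Downstream scripts read these files, so the full pipeline is
exercised through the on-disk interchange format.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from fluxstress.plate import write_plate_run
from fluxstress.simulate import (
    scenario_atp_budget,
    scenario_mito_confound,
    simulate_experiment_set,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    jobs = [
        ("mito_confound", scenario_mito_confound(seed=args.seed), [("MITO", True)]),
        ("atp_budget", scenario_atp_budget(seed=args.seed), [("MITO", False), ("GLYCO", True)]),
    ]
    for name, scenario, kinds in jobs:
        outdir = args.out / name
        outdir.mkdir(parents=True, exist_ok=True)
        n_plates = 0
        for kind, arm_split in kinds:
            for run in simulate_experiment_set(scenario, kind, arm_split=arm_split):
                stem = f"{kind.lower()}_{run.meta['experiment_id']}"
                write_plate_run(run, outdir / f"{stem}_cycles.csv", outdir / f"{stem}_wells.csv")
                n_plates += 1
        truth = dataclasses.asdict(scenario)
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
        print(f"{name}: wrote {n_plates} plates ({scenario.n_experiments} experiments) to {outdir}")


if __name__ == "__main__":
    main()
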