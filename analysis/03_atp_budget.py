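#!/usr/bin/env python
"""Mitochondrial + glycolytic ATP production rates from the simulated runs.

Reads the ATP-budget plates written by 01_simulate_plates.py (CV-inhibited
mito runs for ATP-linked respiration; glyco runs for demand-limited
glycolytic PER), computes per-condition ATP production rates and folds vs
the shared control, and renders the report under results/atp/.
"""

import argparse
from pathlib import Path

from fluxstress.pipeline import AnalysisConfig, load_config, render_report, run_atp_analysis
from fluxstress.plate import ProtocolKind, default_protocol, read_plate_run


def load_runs(simdir: Path, kind: ProtocolKind):
    protocol = default_protocol(kind)
    runs = []
    for cycles in sorted(simdir.glob(f"{kind.value.lower()}_*_cycles.csv")):
        wells = cycles.with_name(cycles.name.replace("_cycles", "_wells"))
        run = read_plate_run(cycles, wells, protocol)
        run.meta["experiment_id"] = run.wells["experiment_id"].iloc[0]
        runs.append(run)
    if not runs:
        raise SystemExit(f"no {kind.value} plates under {simdir}; run 01_simulate_plates.py first")
    return runs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim/atp_budget"))
    ap.add_argument("--out", type=Path, default=Path("results/atp"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--config", type=Path, default=None, help="optional YAML analysis config")
    args = ap.parse_args()
    config = load_config(args.config) if args.config else AnalysisConfig(seed=args.seed)

    report = run_atp_analysis(
        load_runs(args.sim_dir, ProtocolKind.MITO),
        load_runs(args.sim_dir, ProtocolKind.GLYCO),
        config,
    )
    args.out.mkdir(parents=True, exist_ok=True)
    render_report(report, args.out)

    folds = report.atp_folds.set_index(["substance", "dose"])
    print("ATP production rate folds vs control:")
    print(f"  72 ppm Ni: mito {folds.loc[('NI', 72.0), 'mito_atp_fold']:.2f}, "
          f"glyco {folds.loc[('NI', 72.0), 'glyco_atp_fold']:.2f}, "
          f"total {folds.loc[('NI', 72.0), 'total_atp_fold']:.2f}")
    print(f"  LPS: mito {folds.loc[('LPS', 1.0), 'mito_atp_fold']:.2f}, "
          f"glyco {folds.loc[('LPS', 1.0), 'glyco_atp_fold']:.2f}, "
          f"total {folds.loc[('LPS', 1.0), 'total_atp_fold']:.2f}")
    s = report.dose_response["mito_atp"].slope
    print(f"  mito ATP vs Ni: slope {s['estimate']:.3f} pmol ATP/min/1e4 cells per ppm")
    print(f"report written to {args.out}/report.json and report.md")


if __name__ == "__main__":
    main()
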