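#!/usr/bin/env python
"""Full-scale damage-recovery reproduction (long-running; hours on one CPU).

Runs the six-scenario damage batch at the full problem size (3 mm culture,
~2,800 neurons, n = 15 replicates, 72 simulated hours of settling and the
0 min / 15 min / 2 h / 6 h / 24 h recovery schedule) and writes the
burst-ratio-to-control table and its ensemble summary.  The desk-scale
variant of the same pipeline runs inside the test suite; this script exists
for unscaled reproduction runs.

Usage:  python scripts/full_scale_repro.py --seed 0 --out results/full_scale \
            [--replicates 15] [--settle-hours 72]
"""

from __future__ import annotations

import argparse
import logging
from pathlib import Path

import pandas as pd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--replicates", type=int, default=15)
    parser.add_argument("--settle-hours", type=float, default=72.0)
    args = parser.parse_args()

    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(message)s")

    from modsnn import ExperimentConfig
    from modsnn.config import DamageProtocol
    from modsnn.experiment import run_experiment

    cfg = ExperimentConfig(master_seed=args.seed,
                           settle_s=args.settle_hours * 3600.0)
    cfg.protocol = DamageProtocol(n_replicates=args.replicates)
    run_experiment(cfg, args.out)

    table = pd.read_csv(args.out / "burst_ratio_table.csv")
    post = table[table["timepoint"] != "pre"]
    summary = post.groupby(["scenario", "timepoint"], sort=False).agg(
        mean_ratio=("burst_ratio_control", "mean"),
        sd_ratio=("burst_ratio_control", "std"),
        n=("burst_ratio_control", "count"))
    summary.to_csv(args.out / "burst_ratio_summary.csv")
    print(summary.to_string())


if __name__ == "__main__":
    main()
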