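#!/usr/bin/env python
"""Parameter-recovery simulation study on synthetic IVGTT data.

Generates 10 replicate datasets from the IFG pre-surgery archetype (5%
proportional lognormal noise on the 25-point clinical sampling protocol)
and re-estimates insulin sensitivity S_i, insulin degradation d_i and the
secretion delay tau by multistart bound-constrained least squares. Reports
per-replicate and median relative errors; the method is considered to
recover a parameter when the median error is within 15%.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from glifa import NoiseSpec, archetype, fit, generate

OUT = Path(__file__).resolve().parent.parent / "results"
FREE = ("S_i", "d_i", "tau")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--replicates", type=int, default=10)
    args = parser.parse_args()

    arch = archetype("ifg-pre")
    truth = arch.delay
    rows = []
    for rep in range(args.replicates):
        ds = generate(truth, init=arch.init,
                      noise=NoiseSpec(level=0.05, seed=args.seed * 1000 + 100 + rep))
        result = fit(ds, "delay", free=FREE, base=truth, n_starts=3,
                     seed=args.seed * 100 + rep)
        row = {"replicate": rep, "cost": result.cost}
        for k in FREE:
            est = getattr(result.estimates, k)
            row[f"{k}_est"] = est
            row[f"{k}_rel_err"] = abs(est - getattr(truth, k)) / getattr(truth, k)
        rows.append(row)
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "parameter_recovery.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print("\ntruth:", {k: getattr(truth, k) for k in FREE})
    medians = {k: float(np.median(df[f"{k}_rel_err"])) for k in FREE}
    print("median relative errors:", {k: f"{v:.1%}" for k, v in medians.items()})
    print(f"Wrote {OUT / 'parameter_recovery.csv'}")


if __name__ == "__main__":
    main()
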