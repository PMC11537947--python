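#!/usr/bin/env python
"""Compare behavioural and simulated SRT distributions.

For each species, compares the synthetic behavioural distribution with
the simulated batches of every modification step on common 6-ms bins:
R^2 and MSE on the binned proportions, the 1-D Wasserstein (Earth
Mover's) distance, a quantile table and the rank-sum test.  Also tests
the species contrast (marmoset vs human) on both the behavioural and the
simulated side.
"""

import sys
from pathlib import Path

import pandas as pd

from sacfield import io
from sacfield.srt_analysis import compare_samples, rank_sum_test

RESULTS = Path(__file__).resolve().parent.parent / "results"
STEPS = {"marmoset": (1, 2, 3), "human": (1, 2)}


def load(name):
    path = RESULTS / name
    if not path.exists():
        raise SystemExit(f"missing {path}; run earlier analysis steps first")
    return io.table_to_sample(io.read_srt_table(path)).values


def main() -> None:
    rows = []
    for species, steps in STEPS.items():
        observed = load(f"behavior_{species}.csv")
        for step in steps:
            simulated = load(f"model_{species}_step{step}.csv")
            report = compare_samples(observed, simulated)
            io.write_comparison_report(report, RESULTS / f"compare_{species}_step{step}")
            rows.append({"species": species, "step": step, **report.summary()})
            print(
                f"{species} step {step}: R2={report.r_squared:.3f} "
                f"MSE={report.mse:.5f} W={report.wasserstein_ms:.1f} ms"
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "comparison_summary_all.csv", index=False)

    _, p_obs = rank_sum_test(load("behavior_marmoset.csv"), load("behavior_human.csv"))
    _, p_sim = rank_sum_test(
        load("model_marmoset_step3.csv"), load("model_human_step2.csv")
    )
    print(f"species contrast: behavioural p={p_obs:.2e}, simulated p={p_sim:.2e}")
    w = summary.set_index(["species", "step"])["wasserstein_ms"]
    print(
        "marmoset Wasserstein improves step1 -> step3 by "
        f"{w[('marmoset', 1)] / w[('marmoset', 3)]:.2f}x"
    )


if __name__ == "__main__":
    sys.exit(main())
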