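#!/usr/bin/env python
"""Sensitivity analysis: six-month instead of twelve-month follow-up.

Halving the delay to observing the cost-effectiveness endpoint halves the
pipeline (tau = 37 pairwise allocations), which lengthens Stage II and
increases the number of interim analyses at a fixed maximum sample size.
Compares expected sample size with the twelve-month design by simulation.
"""

import argparse
from pathlib import Path

import numpy as np

from vbseq.boundary_solver import solve_boundary
from vbseq.econ_core import DesignParams, PriorSpec
from vbseq.oc_eval import simulate_gaussian_trials, six_month_variant
from vbseq.trial_engine import InterimSchedule

OUT = Path(__file__).resolve().parents[1] / "results"


def main(reps: int, seed: int) -> None:
    params, prior = DesignParams(), PriorSpec()
    oc6 = six_month_variant(params, prior, reps=reps, seed=seed)
    p6 = params.with_(delta_years=0.5, tau=37)
    eps6 = InterimSchedule().decision_epochs(p6)
    eps12 = InterimSchedule().decision_epochs(params)
    print(f"six-month design: tau=37, {len(eps6)} interims "
          f"(vs {len(eps12)} at twelve months)")

    bd12 = solve_boundary(params, prior, thresholds=False)
    res12 = simulate_gaussian_trials(bd12, InterimSchedule(), prior, params,
                                     -45.0, prior.sigma_X, reps,
                                     np.random.default_rng(seed))
    print(f"expected total sample, twelve-month follow-up: "
          f"{res12.total_pairs.mean():6.1f} pairs")
    print(f"expected total sample, six-month follow-up:    "
          f"{oc6.sequential.mean_total_pairs:6.1f} pairs")
    print(f"expected variable-cost saving vs fixed design: "
          f"{oc6.expected_saving:,.0f} pounds")
    OUT.mkdir(exist_ok=True)
    oc6.to_frame().to_csv(OUT / "six_month_oc.csv", index=False)
    print(f"\nwritten: {OUT / 'six_month_oc.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=5_000)
    ap.add_argument("--seed", type=int, default=0)
    a = ap.parse_args()
    main(a.reps, a.seed)
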