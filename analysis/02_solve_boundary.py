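#!/usr/bin/env python
"""Solve the Stage II stopping boundaries for the main analysis.

Computes the boundary for the trial's own maximum (124 pairwise
allocations) and for the doubled maximum (248), together with the
design-selection thresholds: the sequential design is optimal for prior
means strictly between D and C; a one-stage value-of-information design
between C and A (or B and D); and no trial outside A/B.  Boundaries are
exported as CSV + JSON under results/.
"""

import time
from pathlib import Path

from vbseq.boundary_solver import solve_boundary
from vbseq.econ_core import DesignParams, PriorSpec

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params, prior = DesignParams(), PriorSpec()
    OUT.mkdir(exist_ok=True)
    for t_max in (124, 248):
        t0 = time.time()
        bd = solve_boundary(params.with_(T_max=t_max), prior)
        bd.save(OUT / f"boundary_tmax{t_max}.csv")
        print(f"T_max={t_max}: solved in {time.time() - t0:.2f}s; "
              f"Stage II epochs n=1..{bd.n_last}")
        print(f"  no-trial thresholds     A={bd.A:+9.0f}  B={bd.B:+9.0f}")
        print(f"  sequential-design range C={bd.C:+9.0f}  D={bd.D:+9.0f}")
        for n in (1, 10, 20, 30, 40):
            if n <= bd.n_last:
                print(f"  boundary at n={n:3d}: ({bd.lower[n]:+8.0f}, "
                      f"{bd.upper[n]:+8.0f})")
    print(f"\nwritten: {OUT}/boundary_tmax124.csv(.json), "
          f"boundary_tmax248.csv(.json)")


if __name__ == "__main__":
    main()
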