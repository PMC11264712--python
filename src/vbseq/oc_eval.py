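"""Operating-characteristics engines.

Two studies mirror the retrospective evaluation pipeline:

* a resampling study — paths drawn with replacement from a (completed)
  cohort's pairwise INMB values, monitored against the boundary and
  compared with a fixed sample-size design of the same maximum;
* a Gaussian simulation study over a grid of maximum sample sizes T_max,
  drawing i.i.d. Normal(mean, sd^2) INMB streams and recording expected
  sample size and the proportion of paths recruiting to the maximum.

The vectorised Gaussian simulator reproduces ``run_trial`` on the same
stream exactly (the blockwise posterior update is algebraically the batch
update on the running sum); a test pins that equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .boundary_solver import DPConfig, StoppingBoundary, solve_boundary
from .econ_core import DesignParams, PatientRecord, PriorSpec, pairwise_inmb
from .synthetic_data import generate_inmb_stream
from .trial_engine import (ArraySource, InterimSchedule, TrialPath,
                           fixed_design, paths_to_frame, run_trial)


@dataclass(frozen=True)
class DesignStats:
    """Summary of one design over many paths."""

    mean_mu_final: float
    sd_mu_final: float
    min_mu_final: float
    max_mu_final: float
    mean_total_pairs: float
    sd_total_pairs: float
    min_total_pairs: int
    max_total_pairs: int
    prop_adopt_N: float

    @classmethod
    def from_arrays(cls, mu_final: np.ndarray, total: np.ndarray,
                    adopt: np.ndarray) -> "DesignStats":
        return cls(float(mu_final.mean()), float(mu_final.std(ddof=1)),
                   float(mu_final.min()), float(mu_final.max()),
                   float(total.mean()), float(total.std(ddof=1)),
                   int(total.min()), int(total.max()), float(adopt.mean()))


@dataclass(frozen=True)
class OCSummary:
    """Aggregate operating characteristics: sequential vs fixed design."""

    fixed: DesignStats
    sequential: DesignStats
    fixed_n: int
    n_paths: int
    expected_saving: float  # expected variable-cost saving of sequential

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, st in (("fixed", self.fixed), ("sequential", self.sequential)):
            d = {"design": name}
            d.update({k: getattr(st, k) for k in st.__dataclass_fields__})
            rows.append(d)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Resampling study
# ---------------------------------------------------------------------------

def resample_paths(cohort, T_max: int, n_paths: int = 5_000,
                   seed: int | np.random.Generator = 0,
                   lambda_wtp: float = 30_000.0, *,
                   allow_any_tmax: bool = False) -> list[ArraySource]:
    """Bootstrap observation sources from a cohort's pairwise INMB values.

    Each path draws two resamples (with replacement) of the cohort's pairs,
    concatenates and randomly orders them; a path of T_max equal to the
    cohort size is the first half of its double-length construction, so the
    half-length path of a given draw is a prefix of its full-length path.
    ``cohort`` is either a vector of pairwise INMB values or a list of
    complete(d) patient records.
    """
    if isinstance(cohort, (list, tuple)) and cohort and \
            isinstance(cohort[0], PatientRecord):
        xs = np.array([o.x for o in pairwise_inmb(cohort, lambda_wtp)])
    else:
        xs = np.asarray(cohort, dtype=float)
    n = xs.size
    if T_max not in (n, 2 * n) and not allow_any_tmax:
        raise ValueError(
            f"T_max={T_max} is neither the cohort size ({n}) nor double it; "
            "pass allow_any_tmax=True to override")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = []
    for _ in range(n_paths):
        n_res = max(2, -(-T_max // n))  # at least the double construction
        draw = np.concatenate([rng.choice(xs, size=n, replace=True)
                               for _ in range(n_res)])
        rng.shuffle(draw)
        out.append(ArraySource(draw[:T_max]))
    return out


def run_oc(paths: Sequence[ArraySource], boundary: StoppingBoundary,
           schedule: InterimSchedule, prior: PriorSpec, params: DesignParams,
           fixed_n: int) -> OCSummary:
    """Run the sequential and fixed designs on every path and aggregate."""
    seq: list[TrialPath] = []
    fix: list[TrialPath] = []
    for src in paths:
        seq.append(run_trial(src, boundary, schedule, prior, params))
        fix.append(fixed_design(src, fixed_n, prior, params, schedule.block))
    fs, ss = paths_to_frame(fix), paths_to_frame(seq)
    summary = OCSummary(
        fixed=DesignStats.from_arrays(fs.mu_final.to_numpy(),
                                      fs.total_pairs.to_numpy(),
                                      (fs.decision == "adopt_N").to_numpy()),
        sequential=DesignStats.from_arrays(ss.mu_final.to_numpy(),
                                           ss.total_pairs.to_numpy(),
                                           (ss.decision == "adopt_N").to_numpy()),
        fixed_n=fixed_n, n_paths=len(paths),
        expected_saving=float((fixed_n - ss.total_pairs.to_numpy().mean())
                              * params.c))
    return summary


# ---------------------------------------------------------------------------
# Gaussian simulation study
# ---------------------------------------------------------------------------

def simulate_gaussian_trials(boundary: StoppingBoundary,
                             schedule: InterimSchedule, prior: PriorSpec,
                             params: DesignParams, mean: float, sd: float,
                             n_reps: int, rng: np.random.Generator,
                             chunk: int = 500) -> pd.DataFrame:
    """Vectorised sequential monitoring of i.i.d. Gaussian INMB streams.

    Returns one row per replicate (n_stop, total_pairs, mu_final,
    adopt_N, reached_max).  Identical in law and in arithmetic to
    ``run_trial`` on an ``ArraySource`` of the same stream.
    """
    t_max, tau = params.T_max, params.tau
    n0, mu0 = prior.n0, prior.mu0
    epochs = np.array(schedule.decision_epochs(params), dtype=int)
    up = boundary.upper[epochs] if epochs.size else np.empty(0)
    lo = boundary.lower[epochs] if epochs.size else np.empty(0)
    rows = []
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        x = rng.normal(mean, sd, size=(b, t_max))
        cs = np.cumsum(x, axis=1)
        n_stop = np.full(b, t_max - tau)
        active = np.ones(b, dtype=bool)
        for j, n_e in enumerate(epochs):
            mu_n = (n0 * mu0 + cs[:, n_e - 1]) / (n0 + n_e)
            crossed = active & ((mu_n >= up[j]) | (mu_n <= lo[j]))
            n_stop[crossed] = n_e
            active &= ~crossed
        total = np.where(active, t_max, np.minimum(n_stop + tau, t_max))
        mu_final = (n0 * mu0 + cs[np.arange(b), total - 1]) / (n0 + total)
        rows.append(pd.DataFrame({
            "n_stop": np.where(active, t_max - tau, n_stop),
            "total_pairs": total, "mu_final": mu_final,
            "adopt_N": params.P * mu_final > params.I,
            "reached_max": total == t_max}))
        done += b
    return pd.concat(rows, ignore_index=True)


def tmax_grid_study(T_max_list: Sequence[int], reps: int, mean: float,
                    sd: float, params: DesignParams, prior: PriorSpec,
                    seed: int | np.random.Generator = 0,
                    dp: DPConfig | None = None,
                    schedule: InterimSchedule | None = None) -> pd.DataFrame:
    """Expected sample size vs maximum sample size, by simulation.

    For each T_max: solve the boundary, simulate ``reps`` Gaussian INMB
    trials, and record the mean total sample, its ratio to T_max, and the
    proportion of paths recruiting to the maximum.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    schedule = schedule or InterimSchedule()
    out = []
    for t_max in T_max_list:
        p_t = params.with_(T_max=int(t_max))
        bd = solve_boundary(p_t, prior, dp, thresholds=False)
        res = simulate_gaussian_trials(bd, schedule, prior, p_t, mean, sd,
                                       reps, rng)
        out.append({
            "T_max": int(t_max),
            "mean_total_pairs": float(res.total_pairs.mean()),
            "sd_total_pairs": float(res.total_pairs.std(ddof=1)),
            "ratio_to_tmax": float(res.total_pairs.mean() / t_max),
            "prop_reaching_tmax": float(res.reached_max.mean()),
            "prop_adopt_N": float(res.adopt_N.mean()),
            "reps": reps})
    return pd.DataFrame(out)


def six_month_variant(params: DesignParams, prior: PriorSpec,
                      mean: float = -45.0, sd: float | None = None,
                      reps: int = 2_000,
                      seed: int | np.random.Generator = 0,
                      dp: DPConfig | None = None) -> OCSummary:
    """Sensitivity analysis: halve the follow-up delay to six months.

    Re-derives tau for delta = 0.5 years at the same recruitment rate
    (74 -> 37 pairs in the pipeline), re-solves the boundary at the same
    T_max and reruns the Gaussian simulation study.
    """
    tau6 = int(round(params.recruit_rate * 0.5))
    p6 = params.with_(delta_years=0.5, tau=tau6)
    bd = solve_boundary(p6, prior, dp, thresholds=False)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sd = prior.sigma_X if sd is None else sd
    schedule = InterimSchedule()
    res = simulate_gaussian_trials(bd, schedule, prior, p6, mean, sd,
                                   reps, rng)
    seq_stats = DesignStats.from_arrays(res.mu_final.to_numpy(),
                                        res.total_pairs.to_numpy(),
                                        res.adopt_N.to_numpy())
    # fixed design at n = T_max: recompute from fresh streams
    res_f = simulate_gaussian_trials(
        bd, InterimSchedule(first_interim=p6.T_max + 1), prior, p6,
        mean, sd, reps, rng)
    fix_stats = DesignStats.from_arrays(res_f.mu_final.to_numpy(),
                                        res_f.total_pairs.to_numpy(),
                                        res_f.adopt_N.to_numpy())
    return OCSummary(fixed=fix_stats, sequential=seq_stats,
                     fixed_n=p6.T_max, n_paths=reps,
                     expected_saving=float(
                         (p6.T_max - res.total_pairs.mean()) * params.c))
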