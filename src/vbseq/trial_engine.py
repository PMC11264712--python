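"""Run one value-based sequential trial against a stopping boundary.

Stage I recruits ``tau`` pairs before any outcome is observed; Stage II
monitors the posterior mean of E[INMB] at scheduled interims against the
boundary (inclusive first crossing stops recruitment); Stage III follows up
the pipeline pairs, folds their outcomes into the posterior in blocks, and
the adoption decision is taken on the final posterior mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .bayes_update import (BlockEstimate, PosteriorState, initial_state,
                           update_posterior)
from .boundary_solver import StoppingBoundary
from .econ_core import DesignParams, PriorSpec, adoption_decision


@dataclass(frozen=True)
class InterimSchedule:
    """Interim-analysis calendar in observed-pair counts.

    The first interim waits for ``first_interim`` observed pairs (the
    chained-equations imputation needs that much data); later interims run
    every ``block`` pairs.  An epoch is a decision point only while
    recruitment is still open, i.e. while n + tau < T_max.
    """

    first_interim: int = 20
    block: int = 10

    def decision_epochs(self, params: DesignParams) -> list[int]:
        eps = []
        n = self.first_interim
        while n + params.tau < params.T_max:
            eps.append(n)
            n += self.block
        return eps


class ObservationSource(Protocol):
    """Yields by-block INMB estimates in arrival order."""

    n_pairs_available: int

    def block_estimate(self, start: int, end: int) -> BlockEstimate: ...


class ArraySource:
    """Observation source backed by a vector of per-pair INMB values."""

    def __init__(self, x: Sequence[float]):
        self.x = np.asarray(x, dtype=float)
        self.n_pairs_available = int(self.x.size)

    def block_estimate(self, start: int, end: int) -> BlockEstimate:
        if end > self.n_pairs_available:
            raise ValueError(
                f"source exhausted: block [{start}, {end}] requested but only "
                f"{self.n_pairs_available} pairs available")
        return BlockEstimate(block_start=start, block_end=end,
                             estimate=float(self.x[start - 1:end].mean()))


@dataclass
class TrialPath:
    """Trajectory and outcome of one monitored trial."""

    trace: list = field(default_factory=list)  # (n, mu_n, stopped)
    n_stop: int = 0  # observed pairs when recruitment stopped
    total_pairs: int = 0  # n_stop + pipeline, capped at T_max
    mu_final: float = float("nan")
    decision: str = ""
    variable_cost: float = float("nan")
    stopped_early: bool = False

    def to_json(self) -> str:
        return json.dumps({
            "trace": [(int(n), float(mu), bool(s)) for n, mu, s in self.trace],
            "n_stop": self.n_stop, "total_pairs": self.total_pairs,
            "mu_final": self.mu_final, "decision": self.decision,
            "variable_cost": self.variable_cost,
            "stopped_early": self.stopped_early})


def _advance_blocks(state: PosteriorState, source: ObservationSource,
                    upto: int, block: int, prior: PriorSpec) -> PosteriorState:
    """Fold observations (state.n, upto] into the posterior in blocks.

    Full blocks of ``block`` pairs with a final partial block; the very
    first update may be one larger block up to the first interim.
    """
    while state.n < upto:
        end = min(state.n + block, upto)
        state = update_posterior(
            state, source.block_estimate(state.n + 1, end), prior)
    return state


def run_trial(source: ObservationSource, boundary: StoppingBoundary,
              schedule: InterimSchedule, prior: PriorSpec,
              params: DesignParams) -> TrialPath:
    """Monitor one trial: stop at the first interim crossing the boundary.

    The first interim folds all first_interim pairs in as one block (the
    by-block machinery cannot estimate the earliest small blocks); later
    interims add one block each.  After stopping, the pipeline pairs enter
    the posterior in blocks of ``schedule.block`` plus a final partial
    block, and the adoption rule P*mu > I is applied.
    """
    epochs = schedule.decision_epochs(params)
    path = TrialPath()
    state = initial_state(prior)
    stopped_at: int | None = None
    for n_epoch in epochs:
        if n_epoch > source.n_pairs_available:
            raise ValueError(
                f"source exhausted before the schedule completed: interim at "
                f"{n_epoch} pairs, only {source.n_pairs_available} available")
        if state.n == 0:
            state = update_posterior(
                state, source.block_estimate(1, n_epoch), prior)
        else:
            state = _advance_blocks(state, source, n_epoch,
                                    schedule.block, prior)
        stop = boundary.crossed(n_epoch, state.mu_n)
        path.trace.append((n_epoch, state.mu_n, stop))
        if stop:
            stopped_at = n_epoch
            break
    if stopped_at is None:
        # recruitment ran to T_max; observe everything
        path.n_stop = params.T_max - params.tau
        path.total_pairs = params.T_max
        path.stopped_early = False
    else:
        path.n_stop = stopped_at
        path.total_pairs = stopped_at + min(params.tau,
                                            params.T_max - stopped_at)
        path.stopped_early = True
    state = _advance_blocks(state, source, path.total_pairs,
                            schedule.block, prior)
    path.mu_final = state.mu_n
    path.decision = adoption_decision(state.mu_n, params.P, params.I)
    path.variable_cost = path.total_pairs * params.c
    return path


def fixed_design(source: ObservationSource, n_fixed: int, prior: PriorSpec,
                 params: DesignParams, block: int = 10) -> TrialPath:
    """Fixed sample-size comparator: no interim stopping.

    Observes ``n_fixed`` pairs, updates the posterior in blocks, and takes
    the same adoption decision as the sequential design.
    """
    path = TrialPath()
    state = initial_state(prior)
    if n_fixed > 0:
        state = _advance_blocks(state, source, n_fixed, block, prior)
    path.n_stop = n_fixed
    path.total_pairs = n_fixed
    path.mu_final = state.mu_n
    path.decision = adoption_decision(state.mu_n, params.P, params.I)
    path.variable_cost = n_fixed * params.c
    return path


def paths_to_frame(paths: Sequence[TrialPath]) -> pd.DataFrame:
    """Batch of trial paths as one row each (CSV export)."""
    return pd.DataFrame([{
        "n_stop": p.n_stop, "total_pairs": p.total_pairs,
        "mu_final": p.mu_final, "decision": p.decision,
        "variable_cost": p.variable_cost, "stopped_early": p.stopped_early,
    } for p in paths])
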