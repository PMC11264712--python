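"""Conjugate-normal posterior updating of E[INMB] and Rubin's-rules pooling.

The sampling model is X_i ~ Normal(mu_X, sigma_X^2) with sigma_X known, and
the prior mu_X ~ Normal(mu0, sigma_X^2/n0).  After n observed pairwise
allocations with sample mean x-bar,

    mu_n      = (n0*mu0 + n*x_bar) / (n0 + n)
    sigma_n^2 = sigma_X^2 / (n0 + n)

Interim estimates arrive as by-block means (optionally pooled over multiple
imputations); the block mean enters the update weighted by block size, which
is algebraically identical to the batch update on the pooled observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .econ_core import PriorSpec


@dataclass(frozen=True)
class PosteriorState:
    """Posterior for E[INMB] after ``n`` observed pairwise allocations."""

    n: int
    mu_n: float
    sigma_n_sq: float
    sum_x: float = 0.0  # running sum of observed INMB (block_size * block_mean)


@dataclass(frozen=True)
class BlockEstimate:
    """Mean INMB of one block of pairwise allocations, with Rubin components.

    ``total_var = within_var + (1 + 1/m) * between_var``; the variance
    components are diagnostic only — the posterior update treats the
    sampling SD as known.
    """

    block_start: int  # 1-based, inclusive
    block_end: int  # inclusive
    estimate: float
    within_var: float = 0.0
    between_var: float = 0.0
    m_imputations: int = 1

    @property
    def size(self) -> int:
        return self.block_end - self.block_start + 1

    @property
    def total_var(self) -> float:
        if self.m_imputations <= 1:
            return self.within_var
        return self.within_var + (1.0 + 1.0 / self.m_imputations) * self.between_var

    def __post_init__(self) -> None:
        if self.block_end < self.block_start:
            raise ValueError("empty block")


def initial_state(prior: PriorSpec) -> PosteriorState:
    return PosteriorState(n=0, mu_n=prior.mu0,
                          sigma_n_sq=prior.sigma_X ** 2 / prior.n0, sum_x=0.0)


def update_posterior(state: PosteriorState, block: BlockEstimate,
                     prior: PriorSpec) -> PosteriorState:
    """Fold one by-block estimate into the posterior.

    The block must be contiguous with the observations already seen
    (``block_start == state.n + 1``); overlapping or gapped blocks raise.
    """
    if block.block_start != state.n + 1:
        raise ValueError(
            f"block [{block.block_start}, {block.block_end}] not contiguous with "
            f"state.n={state.n}")
    n = state.n + block.size
    sum_x = state.sum_x + block.size * block.estimate
    mu_n = (prior.n0 * prior.mu0 + sum_x) / (prior.n0 + n)
    sigma_n_sq = prior.sigma_X ** 2 / (prior.n0 + n)
    return PosteriorState(n=n, mu_n=mu_n, sigma_n_sq=sigma_n_sq, sum_x=sum_x)


def batch_posterior(xs: Sequence[float], prior: PriorSpec) -> PosteriorState:
    """Posterior computed directly from raw observations (batch oracle)."""
    xs = np.asarray(xs, dtype=float)
    n = xs.size
    sum_x = float(xs.sum())
    mu_n = (prior.n0 * prior.mu0 + sum_x) / (prior.n0 + n)
    return PosteriorState(n=int(n), mu_n=mu_n,
                          sigma_n_sq=prior.sigma_X ** 2 / (prior.n0 + n), sum_x=sum_x)


def rubins_pool(estimates: Sequence[float],
                variances: Sequence[float] | None = None,
                *, block_start: int = 1, block_end: int | None = None) -> BlockEstimate:
    """Pool per-imputation estimates with Rubin's rules.

    ``estimates`` are the m per-imputation point estimates and ``variances``
    their within-imputation variances.  With m == 1 the between-imputation
    variance is undefined and recorded as 0.  Empty input raises.
    """
    q = np.asarray(estimates, dtype=float)
    if q.size == 0:
        raise ValueError("rubins_pool: empty list of estimates")
    m = q.size
    if variances is None:
        w = np.zeros(m)
    else:
        w = np.asarray(variances, dtype=float)
        if w.size != m:
            raise ValueError("estimates and variances differ in length")
    pooled = float(q.mean())
    within = float(w.mean())
    between = float(q.var(ddof=1)) if m >= 2 else 0.0
    if block_end is None:
        block_end = block_start  # size unknown; caller may ignore indices
    return BlockEstimate(block_start=block_start, block_end=block_end,
                         estimate=pooled, within_var=within,
                         between_var=between, m_imputations=int(m))


def sample_sd_inmb(pairs: Sequence[float] | Sequence[Sequence[float]]) -> float:
    """Sample SD of pairwise INMB, pooled over imputations.

    Accepts a single vector of X_i, or one vector per imputation, in which
    case per-imputation SDs are averaged.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] < 2:
        raise ValueError("need at least two pairs to estimate the sampling SD")
    return float(np.mean(np.std(arr, axis=1, ddof=1)))


def trajectory_frame(states: Iterable[PosteriorState]) -> pd.DataFrame:
    """Posterior trajectory as a DataFrame (interim index, n, mu_n, sigma_n)."""
    rows = [{"interim": k, "n": s.n, "mu_n": s.mu_n,
             "sigma_n": float(np.sqrt(s.sigma_n_sq))}
            for k, s in enumerate(states)]
    return pd.DataFrame(rows)
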