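"""Sequential multiple imputation of missing cost and utility fields.

At each interim analysis the records randomised by the data cut are
assembled into a flat table and missing cells are filled by chained
equations: each incomplete variable is regressed on the arm indicator,
the baseline covariates and the other cost/utility fields, with Bayesian
posterior draws of the regression parameters at every sweep so that the
``m`` completed data sets differ in their imputed cells only.  By-block
INMB estimates from the completed sets are pooled with Rubin's rules.

The imputation model is linear-normal throughout, matching the Gaussian
data model of the design; observed cells are never touched, and with no
missing data the pipeline reproduces the complete-data estimates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes_update import BlockEstimate, rubins_pool
from .econ_core import (PatientRecord, UTILITY_MAX, UTILITY_MIN,
                        frame_to_records, pair_records, records_to_frame,
                        derive_costs_and_qalys)


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equations settings.

    ``m`` completed data sets (default 5), ``cycles`` sweeps through the
    incomplete variables per set, linear-normal imputation with posterior
    draws.  ``min_pairs`` guards against the data sparsity that breaks the
    chained-equations fit at very early interims.
    """

    m: int = 5
    cycles: int = 10
    method: str = "linear_normal"
    seed: int = 0
    min_pairs: int = 20

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.cycles < 5:
            raise ValueError("cycles must be >= 5")
        if self.method != "linear_normal":
            raise ValueError(f"unknown imputation method {self.method!r}")


def _imputable_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c in ("u6", "u12") or c.startswith("cost_")]
    return cols


def _design_matrix(df: pd.DataFrame, target: str, cols: Sequence[str]) -> np.ndarray:
    """Predictors: intercept, arm, baseline covariates, u0, other fields."""
    preds = [np.ones(len(df)), (df["arm"] == "N").to_numpy(float)]
    base_like = [c for c in df.columns
                 if c not in ("id", "arm", "rand_date", "u0", "u6", "u12")
                 and not c.startswith("cost_")]
    for c in base_like + ["u0"] + [c for c in cols if c != target]:
        preds.append(df[c].to_numpy(float))
    return np.column_stack(preds)


def _bayes_linear_draw(X: np.ndarray, y: np.ndarray, X_mis: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Posterior-draw linear-normal imputation for one variable.

    Draws sigma^2 from the scaled inverse-chi-square posterior and beta
    from N(beta_hat, sigma^2 (X'X)^-1) (ridge-stabilised), then returns
    X_mis beta* + sigma* eps.
    """
    n, p = X.shape
    ridge = 1e-8 * np.trace(X.T @ X) / p
    xtx = X.T @ X + ridge * np.eye(p)
    beta_hat = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta_hat
    df_res = max(n - p, 2)
    sigma2 = float(resid @ resid) / rng.chisquare(df_res)
    cov = sigma2 * np.linalg.inv(xtx)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return X_mis @ beta_star + np.sqrt(sigma2) * rng.standard_normal(len(X_mis))


def impute_interim(records: Sequence[PatientRecord],
                   cfg: ImputationConfig) -> list[list[PatientRecord]]:
    """Chained-equations imputation of the records available at an interim.

    Returns ``cfg.m`` completed record sets.  Observed values are never
    modified; with no missing data all m sets equal the input exactly.
    Raises if fewer than ``cfg.min_pairs`` complete-able pairs are
    available (data sparsity) or a variable is entirely missing.
    """
    n_pairs = min(sum(1 for r in records if r.arm == "N"),
                  sum(1 for r in records if r.arm == "S"))
    if n_pairs < cfg.min_pairs:
        raise ValueError(
            f"data sparsity: {n_pairs} pairs available, need at least "
            f"{cfg.min_pairs} for a stable chained-equations fit")
    df = records_to_frame(list(records))
    cols = _imputable_columns(df)
    miss = {c: df[c].isna().to_numpy() for c in cols}
    for c in cols:
        if miss[c].all():
            raise ValueError(f"variable {c!r} is entirely missing; cannot impute")
    if not any(m.any() for m in miss.values()):
        return [list(records) for _ in range(cfg.m)]

    rng = np.random.default_rng(cfg.seed)
    completed: list[list[PatientRecord]] = []
    incomplete = [c for c in cols if miss[c].any()]
    for _ in range(cfg.m):
        work = df.copy()
        # initialise missing cells from draws of the observed marginal
        for c in incomplete:
            obs = work.loc[~miss[c], c].to_numpy(float)
            work.loc[miss[c], c] = rng.choice(obs, size=int(miss[c].sum()),
                                              replace=True)
        for _cycle in range(cfg.cycles):
            for c in incomplete:
                X_all = _design_matrix(work, c, cols)
                y_obs = df.loc[~miss[c], c].to_numpy(float)
                draws = _bayes_linear_draw(X_all[~miss[c]], y_obs,
                                           X_all[miss[c]], rng)
                work.loc[miss[c], c] = draws
        # imputed utilities must respect the EQ-5D value-set range
        for c in ("u6", "u12"):
            if c in incomplete:
                work.loc[miss[c], c] = work.loc[miss[c], c].clip(
                    UTILITY_MIN, UTILITY_MAX)
        completed.append(frame_to_records(work))
    return completed


def by_block_estimates(completed: Sequence[Sequence[PatientRecord]],
                       block_start: int, block_end: int,
                       lambda_wtp: float,
                       delta_years: float = 1.0) -> BlockEstimate:
    """Pooled mean INMB of pairs ``block_start..block_end`` (1-based).

    Per completed data set, patients are paired by within-arm arrival
    rank, pairwise INMB computed for the block, and the per-imputation
    block means pooled with Rubin's rules.
    """
    if block_end < block_start:
        raise ValueError("empty block")
    means, variances = [], []
    for recset in completed:
        pairs = pair_records(list(recset))
        if len(pairs) < block_end:
            raise ValueError(
                f"block [{block_start}, {block_end}] extends beyond the "
                f"{len(pairs)} available pairs")
        xs = []
        for pr in pairs[block_start - 1:block_end]:
            c_n, e_n = derive_costs_and_qalys(pr[0], delta_years)
            c_s, e_s = derive_costs_and_qalys(pr[1], delta_years)
            xs.append(lambda_wtp * (e_n - e_s) - (c_n - c_s))
        xs = np.asarray(xs)
        means.append(float(xs.mean()))
        variances.append(float(xs.var(ddof=1) / xs.size) if xs.size > 1 else 0.0)
    return rubins_pool(means, variances,
                       block_start=block_start, block_end=block_end)


class MISource:
    """Observation source driving interim monitoring from a patient cohort.

    For a block request ending at pair ``end``, the calendar data cut is
    the follow-up completion date of that pair.  Records randomised by the
    cut enter the imputation data set; fields whose measurement date lies
    beyond the cut are masked as not-yet-observed before imputation, so no
    future data can leak into an interim estimate.
    """

    def __init__(self, records: Sequence[PatientRecord], lambda_wtp: float,
                 delta_years: float = 1.0,
                 cfg: ImputationConfig | None = None):
        self.cfg = cfg or ImputationConfig()
        self.lambda_wtp = lambda_wtp
        self.delta_years = delta_years
        self.records = list(records)
        self.pairs = pair_records(self.records)
        self.n_pairs_available = len(self.pairs)

    def _cut_date(self, end: int) -> float:
        rec_n, rec_s = self.pairs[end - 1]
        return max(rec_n.rand_date, rec_s.rand_date) + 365.0 * self.delta_years

    def _records_at_cut(self, cut: float) -> list[PatientRecord]:
        """Records randomised by the cut, follow-up fields masked to date."""
        import copy
        out = []
        half = 365.0 * self.delta_years / 2.0
        full = 365.0 * self.delta_years
        for r in self.records:
            if r.rand_date > cut:
                continue
            rr = copy.deepcopy(r)
            if r.rand_date + half > cut:
                rr.utilities[1] = None
            if r.rand_date + full > cut:
                rr.utilities[2] = None
                rr.cost_components = [None] * len(rr.cost_components)
            out.append(rr)
        return out

    def block_estimate(self, start: int, end: int) -> BlockEstimate:
        if end > self.n_pairs_available:
            raise ValueError(
                f"source exhausted: block [{start}, {end}] requested but only "
                f"{self.n_pairs_available} pairs available")
        cut = self._cut_date(end)
        avail = self._records_at_cut(cut)
        cfg = ImputationConfig(m=self.cfg.m, cycles=self.cfg.cycles,
                               method=self.cfg.method,
                               seed=self.cfg.seed + 7919 * end,
                               min_pairs=self.cfg.min_pairs)
        completed = impute_interim(avail, cfg)
        return by_block_estimates(completed, start, end, self.lambda_wtp,
                                  self.delta_years)
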