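"""Economic primitives of the value-based sequential trial design.

Domain types (design parameters, prior, patient records, paired INMB
observations) and the operations that turn patient-level cost/utility data
into pairwise incremental net monetary benefit (INMB):

    NB_ij  = lambda * E_ij - C_ij          net benefit of technology j, pair i
    X_i    = NB_iN - NB_iS                 pairwise INMB; positive favours N

where E is a QALY measure derived from EQ-5D-style utilities and C the total
follow-up cost.  Money is represented as real pounds throughout; rounding
happens only at reporting time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: EQ-5D value-set range for a single utility assessment.
UTILITY_MIN = -0.594
UTILITY_MAX = 1.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignParams:
    """Economic and logistical constants of the trial design.

    Attributes
    ----------
    lambda_wtp:
        Maximum willingness to pay for one QALY (pounds/QALY).
    P:
        Number of patients affected by the adoption decision.
    horizon_years, annual_incidence:
        Optional provenance of ``P`` (P = annual_incidence * horizon_years).
    I:
        One-off cost of switching from the standard to the new technology.
    c:
        Variable research cost per pairwise allocation.
    fixed_cost_pre, fixed_cost_during, fixed_cost_post:
        Fixed research spend before, during and after the recruitment /
        follow-up window.
    delta_years:
        Follow-up delay for the cost-effectiveness endpoint, in years.
    recruit_rate:
        Pairwise allocations per year.
    tau:
        Follow-up delay expressed in pairwise allocations
        (tau = round(recruit_rate * delta_years)).
    T_max:
        Maximum number of pairwise allocations.
    trial_days:
        Calendar duration of recruitment.
    """

    lambda_wtp: float = 30_000.0
    P: float = 24_500.0
    I: float = 0.0
    c: float = 1_650.0
    fixed_cost_pre: float = 90_216.0
    fixed_cost_during: float = 204_581.0
    fixed_cost_post: float = 336_042.0
    delta_years: float = 1.0
    recruit_rate: float = 74.0
    tau: int = 74
    T_max: int = 124
    trial_days: float = 611.0
    horizon_years: float | None = 10.0
    annual_incidence: float | None = 2_450.0

    def __post_init__(self) -> None:
        for name in ("lambda_wtp", "P", "I", "c", "fixed_cost_pre",
                     "fixed_cost_during", "fixed_cost_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.T_max > self.tau > 0):
            raise ValueError(
                f"require T_max > tau > 0, got T_max={self.T_max}, tau={self.tau}")

    @property
    def fixed_cost_total(self) -> float:
        return self.fixed_cost_pre + self.fixed_cost_during + self.fixed_cost_post

    def with_(self, **kwargs) -> "DesignParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior on E[INMB] with known sampling SD.

    ``n0`` is the prior's effective sample size in pairwise allocations:
    sigma0_sq = sigma_X**2 / n0.
    """

    mu0: float = 0.0
    sigma_X: float = 7_615.0
    n0: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_X <= 0:
            raise ValueError("sigma_X must be positive")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")

    @property
    def sigma0_sq(self) -> float:
        return self.sigma_X ** 2 / self.n0


@dataclass
class PatientRecord:
    """One patient's randomisation and follow-up data.

    ``utilities`` holds EQ-5D-style utilities at months 0, 6 and 12; missing
    entries are ``None`` (or NaN when read from CSV).  ``cost_components``
    are follow-up cost items in pounds.  ``baseline_covariates`` are numeric
    covariates available at randomisation and used by the imputation model.
    """

    id: str
    arm: str  # "N" (new technology) or "S" (standard/placebo)
    rand_date: float  # days since trial start
    utilities: list  # [u0, u6, u12], entries may be None/NaN
    cost_components: list  # entries may be None/NaN
    baseline_covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ("N", "S"):
            raise ValueError(f"arm must be 'N' or 'S', got {self.arm!r}")
        for u in self.utilities:
            if u is not None and np.isfinite(u) and not (UTILITY_MIN <= u <= UTILITY_MAX):
                raise ValueError(
                    f"utility {u} outside EQ-5D range [{UTILITY_MIN}, {UTILITY_MAX}]")


@dataclass(frozen=True)
class PairedObservation:
    """One pairwise INMB observation X_i."""

    pair_index: int  # 1-based
    x: float  # pounds
    arrival_order: int  # rank by randomisation date


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _require_complete(record: PatientRecord) -> None:
    for k, u in enumerate(record.utilities):
        if u is None or not np.isfinite(u):
            raise ValueError(f"record {record.id}: missing utility u{(0, 6, 12)[k]}")
    for k, ci in enumerate(record.cost_components):
        if ci is None or not np.isfinite(ci):
            raise ValueError(f"record {record.id}: missing cost component cost_{k + 1}")


def derive_costs_and_qalys(record: PatientRecord,
                           delta_years: float = 1.0) -> tuple[float, float]:
    """Total follow-up cost and QALYs for one complete patient record.

    QALYs are the trapezoidal area under the utility curve at months 0,
    6 and 12, scaled to the follow-up window of ``delta_years`` years
    (measurement times 0, delta/2, delta).  Total cost is the sum of the
    cost components.  Raises ``ValueError`` naming the field if anything
    is missing or a utility is out of range.
    """
    _require_complete(record)
    u0, u6, u12 = (float(u) for u in record.utilities)
    for u in (u0, u6, u12):
        if not (UTILITY_MIN <= u <= UTILITY_MAX):
            raise ValueError(f"utility {u} outside [{UTILITY_MIN}, {UTILITY_MAX}]")
    # trapezoid on an even two-interval grid: weights 1/4, 1/2, 1/4
    qaly = delta_years * (0.25 * u0 + 0.5 * u6 + 0.25 * u12)
    total_cost = float(sum(record.cost_components))
    return total_cost, qaly


def compute_inmb(pair: tuple[PatientRecord, PatientRecord],
                 lambda_wtp: float,
                 delta_years: float = 1.0) -> float:
    """Pairwise INMB  x = lambda*(E_N - E_S) - (C_N - C_S).

    ``pair`` is (new-technology record, standard record); both must be
    complete.  Positive values favour the new technology.
    """
    rec_n, rec_s = pair
    if rec_n.arm != "N" or rec_s.arm != "S":
        raise ValueError(
            f"mismatched arms: expected ('N', 'S'), got ({rec_n.arm!r}, {rec_s.arm!r})")
    c_n, e_n = derive_costs_and_qalys(rec_n, delta_years)
    c_s, e_s = derive_costs_and_qalys(rec_s, delta_years)
    return lambda_wtp * (e_n - e_s) - (c_n - c_s)


def adoption_decision(mu_final: float, P: float, I: float) -> str:
    """Final technology adoption rule: adopt N iff P*mu_final > I.

    Ties resolve to the status quo (keep_S): a strict inequality is
    required before recommending a switch.
    """
    return "adopt_N" if P * mu_final > I else "keep_S"


def cost_accounting(pairs_recruited: int, params: DesignParams) -> tuple[float, float]:
    """Variable and total research spend for a given recruitment count.

    ``variable`` = pairs * c; ``total`` adds all fixed-cost components.
    """
    if pairs_recruited < 0:
        raise ValueError("pairs_recruited must be non-negative")
    if pairs_recruited > params.T_max:
        raise ValueError(
            f"pairs_recruited={pairs_recruited} exceeds T_max={params.T_max}")
    variable = pairs_recruited * params.c
    total = variable + params.fixed_cost_total
    return variable, total


def derive_params(*,
                  total_pairs: int,
                  trial_days: float,
                  delta_years: float = 1.0,
                  variable_spend: float | None = None,
                  annual_incidence: float | None = None,
                  horizon_years: float | None = None,
                  T_max: int | None = None,
                  **overrides) -> DesignParams:
    """Derive design parameters from raw accounts, incidence and rates.

    * recruit_rate = total_pairs / (trial_days/365)   (pairs per year)
    * tau = round(recruit_rate * delta_years)
    * c   = variable_spend / total_pairs, rounded to the nearest pound
    * P   = annual_incidence * horizon_years
    """
    if trial_days <= 0:
        raise ValueError("trial_days must be positive")
    if total_pairs <= 0:
        raise ValueError("total_pairs must be positive")
    recruit_rate = total_pairs / (trial_days / 365.0)
    tau = int(round(recruit_rate * delta_years))
    kwargs: dict = dict(delta_years=delta_years, recruit_rate=recruit_rate,
                        tau=tau, trial_days=trial_days)
    if variable_spend is not None:
        kwargs["c"] = float(round(variable_spend / total_pairs))
    if annual_incidence is not None and horizon_years is not None:
        kwargs["P"] = annual_incidence * horizon_years
        kwargs["annual_incidence"] = annual_incidence
        kwargs["horizon_years"] = horizon_years
    kwargs["T_max"] = T_max if T_max is not None else total_pairs
    kwargs.update(overrides)
    return DesignParams(**kwargs)


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def pair_records(records: Sequence[PatientRecord]) -> list[tuple[PatientRecord, PatientRecord]]:
    """Pair N and S patients by within-arm rank of randomisation date.

    Surplus patients in the longer arm are dropped with a warning.  The
    returned list is ordered by pair arrival (rank).
    """
    arm_n = sorted((r for r in records if r.arm == "N"), key=lambda r: (r.rand_date, r.id))
    arm_s = sorted((r for r in records if r.arm == "S"), key=lambda r: (r.rand_date, r.id))
    k = min(len(arm_n), len(arm_s))
    if len(arm_n) != len(arm_s):
        logger.warning(
            "unbalanced arms (N=%d, S=%d): dropping %d surplus record(s)",
            len(arm_n), len(arm_s), abs(len(arm_n) - len(arm_s)))
    return list(zip(arm_n[:k], arm_s[:k]))


def pairwise_inmb(records: Sequence[PatientRecord],
                  lambda_wtp: float,
                  delta_years: float = 1.0) -> list[PairedObservation]:
    """All pairwise INMB observations of a cohort, in arrival order."""
    pairs = pair_records(records)
    out = []
    for i, pr in enumerate(pairs, start=1):
        out.append(PairedObservation(pair_index=i,
                                     x=compute_inmb(pr, lambda_wtp, delta_years),
                                     arrival_order=i))
    return out


# ---------------------------------------------------------------------------
# External interfaces (CSV / YAML)
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Patient records as a flat DataFrame (CSV dialect of the package).

    Columns: id, arm, rand_date, u0, u6, u12, cost_1..cost_k, then one
    column per baseline covariate.
    """
    n_cost = max((len(r.cost_components) for r in records), default=0)
    cov_names = sorted({k for r in records for k in r.baseline_covariates})
    rows = []
    for r in records:
        row: dict = {"id": r.id, "arm": r.arm, "rand_date": r.rand_date,
                     "u0": r.utilities[0], "u6": r.utilities[1], "u12": r.utilities[2]}
        for k in range(n_cost):
            row[f"cost_{k + 1}"] = (r.cost_components[k]
                                    if k < len(r.cost_components) else np.nan)
        for name in cov_names:
            row[name] = r.baseline_covariates.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    cost_cols = sorted((c for c in df.columns if c.startswith("cost_")),
                       key=lambda c: int(c.split("_")[1]))
    base_cols = {"id", "arm", "rand_date", "u0", "u6", "u12", *cost_cols}
    cov_cols = [c for c in df.columns if c not in base_cols]
    records = []
    for _, row in df.iterrows():
        records.append(PatientRecord(
            id=str(row["id"]), arm=str(row["arm"]), rand_date=float(row["rand_date"]),
            utilities=[None if pd.isna(row[c]) else float(row[c])
                       for c in ("u0", "u6", "u12")],
            cost_components=[None if pd.isna(row[c]) else float(row[c])
                             for c in cost_cols],
            baseline_covariates={c: float(row[c]) for c in cov_cols},
        ))
    return records


def write_records_csv(records: Sequence[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[PatientRecord]:
    return frame_to_records(pd.read_csv(path))


_PARAM_KEYS = {f.name for f in DesignParams.__dataclass_fields__.values()}  # type: ignore[attr-defined]
_PRIOR_KEYS = {"mu0", "sigma_X", "n0"}


def load_config(path) -> tuple[DesignParams, PriorSpec]:
    """Read DesignParams and PriorSpec from a flat key-value YAML file.

    Keys mirror the design-parameter names (lambda_wtp, P, I, c, tau,
    T_max, ...; mu0, sigma_X, n0).  Unknown keys raise; sigma_X, tau and
    T_max have no silent defaults and must be present.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _PARAM_KEYS - _PRIOR_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for required in ("sigma_X", "tau", "T_max"):
        if required not in raw:
            raise ValueError(f"config must set {required!r} explicitly")
    params = DesignParams(**{k: v for k, v in raw.items() if k in _PARAM_KEYS})
    prior = PriorSpec(**{k: v for k, v in raw.items() if k in _PRIOR_KEYS})
    return params, prior


def dump_config(params: DesignParams, prior: PriorSpec, path) -> None:
    data = {k: getattr(params, k) for k in sorted(_PARAM_KEYS)
            if getattr(params, k) is not None}
    data.update({k: getattr(prior, k) for k in sorted(_PRIOR_KEYS)})
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
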