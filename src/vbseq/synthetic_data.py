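"""Synthetic HERO-like cohorts with configurable cost-effectiveness truth.

Generates patient-level records (EQ-5D-style utilities at 0/6/12 months,
Gaussian follow-up cost components, MAR missingness driven by observed
baseline covariates) calibrated so that the derived pairwise incremental
net monetary benefit is exactly Normal(true_mean_inmb, sd_inmb^2).

Patient model (per patient, arm indicator a in {0: standard, 1: new}):

    z ~ N(0,1)   latent-free health propensity (observed baseline covariate)
    w ~ N(0,1)   standardised age (observed, prognostically inert)
    u_t  = u_mean + du*a*1[t>0] + u_z*z + u_e*eps_t        t in {0, 6, 12}
    c_j  = c_mean_j + dc_j*a - c_z*z + s_c*eps_j           j = 1..k

QALY is the trapezoid 0.25*u0 + 0.5*u6 + 0.25*u12, so the arm effect on
QALYs is 0.75*du.  All stochastic terms are Gaussian, hence the pairwise
INMB  lambda*(E_N - E_S) - (C_N - C_S)  is Gaussian; the common cost-
component scale s_c is solved analytically so its SD hits ``sd_inmb``.

Missingness applies to u6, u12 and the cost components only (baseline
fields are always observed) with logistic probability in (z, arm, z*arm):
MAR by construction, since the driver covariates are fully observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .econ_core import PatientRecord, UTILITY_MIN, UTILITY_MAX


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions emulated by the generator.

    Defaults reproduce the trial this package's worked examples are built
    around: 124 pairs recruited uniformly over 611 days, pairwise INMB
    approximately Normal(-45, 7615^2) at lambda = 30,000 pounds/QALY.
    """

    n_pairs: int = 124
    trial_days: float = 611.0
    true_mean_inmb: float = -45.0
    sd_inmb: float = 7_615.0
    lambda_wtp: float = 30_000.0
    # utility model
    utility_mean: float = 0.65
    utility_z_sd: float = 0.06  # loading on the shared health covariate z
    utility_noise_sd: float = 0.08  # per-assessment noise
    qaly_arm_effect: float = 0.001  # QALYs gained on the new technology
    # cost model
    n_cost_components: int = 3
    cost_means: tuple = (600.0, 900.0, 1_500.0)
    cost_z_loading: float = 800.0  # pounds per unit z (healthier -> cheaper)
    # arm effect on total cost is implied: lambda*qaly_arm_effect - true_mean_inmb
    # missingness (marginal MAR rates per field; baseline fields stay observed)
    missing_rates: dict = field(default_factory=lambda: {
        "u6": 0.15, "u12": 0.25, "cost_1": 0.30, "cost_2": 0.30, "cost_3": 0.30})
    miss_beta_z: float = -0.8  # healthier patients less likely to be missing
    miss_beta_arm: float = 0.5
    miss_beta_zarm: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cost_means) != self.n_cost_components:
            raise ValueError("cost_means length must equal n_cost_components")
        for f_, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {f_} outside [0, 1]: {r}")

    @property
    def cost_arm_effect(self) -> float:
        """Total extra cost on the new arm implied by the INMB target."""
        return self.lambda_wtp * self.qaly_arm_effect - self.true_mean_inmb

    def qaly_variance(self) -> float:
        # z is shared across the three assessments; noise is independent
        return self.utility_z_sd ** 2 + 0.375 * self.utility_noise_sd ** 2

    def component_noise_sd(self) -> float:
        """Solve the per-component cost noise SD hitting the INMB SD target.

        Pairwise Var(INMB) = 2 * [lambda^2 VarE + VarC - 2 lambda Cov(E, C)]
        with Cov(E, C) = -utility_z_sd * cost_z_loading.  Raises if the
        utility and covariate scales already exceed the target.
        """
        lam = self.lambda_wtp
        var_needed = (self.sd_inmb ** 2 / 2.0
                      - lam ** 2 * self.qaly_variance()
                      - self.cost_z_loading ** 2
                      - 2.0 * lam * self.utility_z_sd * self.cost_z_loading)
        if var_needed <= 0:
            raise ValueError(
                "infeasible calibration: sd_inmb too small for the utility and "
                "covariate scales")
        return math.sqrt(var_needed / self.n_cost_components)

    def implied_inmb_sd(self) -> float:
        """Forward check of the calibration (should equal sd_inmb)."""
        lam, s_c = self.lambda_wtp, self.component_noise_sd()
        var_c = self.n_cost_components * s_c ** 2 + self.cost_z_loading ** 2
        cov_ec = -self.utility_z_sd * self.cost_z_loading
        return math.sqrt(2 * (lam ** 2 * self.qaly_variance() + var_c
                              - 2 * lam * cov_ec))


def _calibrate_intercept(rate: float, cfg: GeneratorConfig) -> float:
    """Logistic intercept so the marginal missingness rate equals ``rate``.

    Averages the logistic over z ~ N(0,1) (Gauss-Hermite) and the two arms.
    """
    if rate <= 0.0:
        return -math.inf
    if rate >= 1.0:
        return math.inf
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()

    def marginal(alpha: float) -> float:
        p = 0.0
        for a in (0.0, 1.0):
            eta = (alpha + cfg.miss_beta_z * nodes + cfg.miss_beta_arm * a
                   + cfg.miss_beta_zarm * a * nodes)
            p += 0.5 * float(weights @ special.expit(eta))
        return p - rate

    return float(optimize.brentq(marginal, -25.0, 25.0))


def generate_cohort(cfg: GeneratorConfig) -> list[PatientRecord]:
    """Draw a full synthetic cohort of 2*n_pairs patient records."""
    s_c = cfg.component_noise_sd()  # validates calibration
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    du = cfg.qaly_arm_effect / 0.75
    cost_shares = np.asarray(cfg.cost_means) / sum(cfg.cost_means)
    dc = cfg.cost_arm_effect * cost_shares

    alphas = {f_: _calibrate_intercept(r, cfg)
              for f_, r in cfg.missing_rates.items()}

    records: list[PatientRecord] = []
    for arm, a in (("N", 1.0), ("S", 0.0)):
        dates = rng.uniform(0.0, cfg.trial_days, size=n)
        z = rng.standard_normal(n)
        w = rng.standard_normal(n)
        eps_u = rng.standard_normal((n, 3))
        u = (cfg.utility_mean + cfg.utility_z_sd * z[:, None]
             + cfg.utility_noise_sd * eps_u)
        u[:, 1:] += du * a
        u = np.clip(u, UTILITY_MIN, UTILITY_MAX)
        # cost_z_loading is the loading on TOTAL cost; split across components
        costs = (np.asarray(cfg.cost_means)[None, :] + dc[None, :] * a
                 - (cfg.cost_z_loading / cfg.n_cost_components) * z[:, None]
                 + s_c * rng.standard_normal((n, cfg.n_cost_components)))
        # MAR masks from observed covariates only
        masks = {}
        for f_, alpha in alphas.items():
            eta = (alpha + cfg.miss_beta_z * z + cfg.miss_beta_arm * a
                   + cfg.miss_beta_zarm * a * z)
            masks[f_] = rng.uniform(size=n) < special.expit(eta)
        for i in range(n):
            utilities = [float(u[i, 0]),
                         None if masks.get("u6", np.zeros(n, bool))[i] else float(u[i, 1]),
                         None if masks.get("u12", np.zeros(n, bool))[i] else float(u[i, 2])]
            comps = []
            for j in range(cfg.n_cost_components):
                m = masks.get(f"cost_{j + 1}", np.zeros(n, bool))[i]
                comps.append(None if m else float(costs[i, j]))
            records.append(PatientRecord(
                id=f"{arm}{i + 1:04d}", arm=arm, rand_date=float(dates[i]),
                utilities=utilities, cost_components=comps,
                baseline_covariates={"health_z": float(z[i]),
                                     "age_std": float(w[i])}))
    return records


def true_values(records: list[PatientRecord], cfg: GeneratorConfig) -> dict:
    """Not used by the pipeline; retained for oracle-style checks in tests."""
    return {"mean_inmb": cfg.true_mean_inmb, "sd_inmb": cfg.implied_inmb_sd()}


def generate_inmb_stream(n: int, mean: float, sd: float,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """I.i.d. Gaussian pairwise INMB draws, bypassing the patient layer.

    Used by the simulation studies, where whole trials are driven directly
    from the Gaussian sampling model.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.normal(mean, sd, size=n)
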