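# Methods

## The decision problem

Two technologies are compared on cost-effectiveness grounds in a randomised
trial that allocates patients in pairs (one per arm). For pair *i* the
incremental net monetary benefit (INMB) is

    X_i = λ (E_iN − E_iS) − (C_iN − C_iS),

with *E* the QALYs and *C* the total cost accrued over the follow-up window
and λ the payer's willingness to pay per QALY. The X_i are modelled as
i.i.d. Normal(μ_X, σ_X²) with σ_X known; beliefs about μ_X are conjugate
Normal, parameterised by a prior mean μ₀ and an effective prior sample size
n₀ = σ_X²/σ₀². After n observed pairs with sample mean x̄,

    μ_n = (n₀ μ₀ + n x̄)/(n₀ + n),   σ_n² = σ_X²/(n₀ + n).

The trial has three stages. During Stage I, τ pairs are recruited before
any outcome has completed follow-up (τ = recruitment rate × follow-up
delay, in pairwise allocations). During Stage II each observed outcome
updates the posterior and recruitment may stop; whenever recruitment is
open, τ recruited-but-unobserved "pipeline" pairs are in the system.
During Stage III the pipeline completes follow-up and the adoption rule
*adopt the new technology iff P·μ_final > I* is applied, where P is the
population affected by the decision and I a one-off switching cost. Ties
resolve to the incumbent.

## The stopping boundary

The state during Stage II is (n, μ_n). Stopping at n still yields
m = min(τ, T_max − n) further observations, so the value of stopping is
the preposterior expectation

    stop(n, μ) = E[ max(P μ' − I, 0) ],   μ' ~ Normal(μ, s²),
    s = preposterior_sd(n, m) = σ_X sqrt( m / ((n₀+n)(n₀+n+m)) ),

with the standard closed form P[(μ − I/P)Φ(z) + s φ(z)], z = (μ − I/P)/s.
Continuing recruits one more pair at cost c and observes one more outcome;
the posterior mean then moves by a Gaussian step with SD
preposterior_sd(n, 1). Backward induction over n = (T_max − τ) … 0 gives

    V(n, μ) = max( stop(n, μ),  −c + E[ V(n+1, μ + ξ) ] ),

with terminal value stop(T_max − τ, μ). The stopping boundary is the locus
where the two branches cross; interim monitoring applies it only at
scheduled interims (solver and schedule are deliberately separated).

### Numerics

* μ grid: half-width £60,000, step £50 (defaults). The half-width must
  cover the outermost design threshold plus several prior SDs; the solver
  raises if the continuation region ever touches the grid edge.
* The continuation expectation is a discrete convolution against a
  truncated Gaussian kernel (±6 SD). When the one-step transition SD falls
  below one grid step — which happens for n ≳ 150 at the default scales —
  a sampled Gaussian kernel loses most of its variance and would
  systematically undervalue continuation, so a three-point kernel matching
  the first two moments exactly is used there instead.
* Boundary values are linearly interpolated between the bracketing grid
  nodes; epochs where continuation is optimal across the whole grid carry
  ±∞ sentinels, and epochs with an empty continuation region collapse both
  boundary values to the adoption indifference point I/P.
* Crossing at an interim is inclusive (a posterior mean exactly on the
  boundary stops): "crossed" is ambiguous at equality and the inclusive
  rule is conservative on sampling cost.
* Halving the grid step changes boundary values by well under £100
  everywhere (pinned by a test); Bellman residuals at stored grid nodes
  are below £1; Monte-Carlo evaluation of the computed policy reproduces
  the root value within Monte-Carlo error and dominates every fixed
  stopping time on a coarse grid.

### Design selection (points A–D)

Before the trial, three designs are compared as functions of the prior
mean μ₀: no trial (value max(P μ₀ − I, 0)); the best one-stage fixed
design (expected net benefit of sampling, ENBS, maximised over its sample
size); and the sequential design (root DP value net of the Stage I
commitment c·τ). A and B are the prior means at which the best one-stage
ENBS crosses zero; C and D are where the sequential design stops
dominating the one-stage design. Two choices matter here, and both are
this package's own calls where the allocation was genuinely open:

* **Only variable research costs enter the design comparison.** Fixed
  research costs are treated as incurred whichever design is chosen, so
  they cancel from the comparison. Charging the pre-trial fixed spend to
  the trial designs moves A/B inward by roughly £2,000 at the default
  parameters; the variable-cost-only convention reproduces the intended
  threshold structure and keeps A/B independent of how overheads are
  split. The fixed-cost fields remain in `DesignParams` and are used by
  the cost-accounting reports.
* **The one-stage comparator shares the trial's recruitment ceiling**
  (its sample size is capped at T_max; `DPConfig.one_stage_n_cap`
  overrides). Left uncapped, the one-stage design's optimal sample size
  near μ₀ = 0 exceeds T_max and it dominates the sequential design
  everywhere, collapsing C/D; under a common ceiling the sequential
  design's adaptivity makes it strictly better for equivocal priors.

With the default (Table-style) parameters and T_max = 124 this yields
C/D ≈ ±£11,900 and A/B ≈ ±£16,100.

## Interim monitoring and multiple imputation

Interims occur every 10 observed pairs, the first at 20: the
chained-equations fit is unstable on fewer pairs (the engine refuses to
impute below `min_pairs = 20`). The final scheduled epoch must satisfy
n + τ < T_max — at n = T_max − τ recruitment is already complete, so it is
not a decision point. This gives 3 interims at T_max = 124 with τ = 74,
and 16 at T_max = 248.

At each interim, all records randomised by the calendar data cut (the
follow-up completion date of the most recent pair) enter the imputation
data set; fields not yet measured at the cut are masked, so no future
information can leak backwards. Missing cost components and utilities are
imputed by chained equations — Bayesian linear-normal regressions with
posterior-draw parameters at every sweep, conditioning on arm, baseline
covariates, baseline utility and the other cost/utility fields — m = 5
completed data sets by default, 10 sweeps each. Imputed utilities are
clamped to the EQ-5D value-set range [−0.594, 1]. Imputation is applied to
costs and utilities, not to INMB directly; QALYs (trapezoidal area under
the 0/6/12-month utilities) and INMB are then derived per completed set,
mirroring the derivation order of a standard trial economic analysis.

The per-imputation means of the most recent block of pairs are pooled by
Rubin's rules (pooled mean; total variance = within + (1 + 1/m)·between).
The pooled block mean enters the conjugate update weighted by block size —
algebraically identical to the batch update on the pooled observations.
The known-variance model uses σ_X for the posterior; the Rubin variance is
carried for diagnostics only. With m = 1 or no missing cells the pipeline
reproduces the complete-data estimates bit for bit.

## Synthetic cohorts

No public patient-level data exist for this design's motivating trial, so
the generator is a first-class module emulating its study conditions: 124
pairs recruited uniformly over 611 days, pairwise INMB approximately
Normal(−£45, £7,615²) at λ = £30,000 — an equivocal cost-effectiveness
signal.

Per patient: a standard-normal health covariate z (observed at baseline)
loads positively on utilities (SD 0.06) and negatively on total cost
(£800 per unit z); utilities at 0/6/12 months share z and carry
independent per-assessment noise (SD 0.08) around a baseline mean of 0.65;
three Gaussian cost components (means £600/£900/£1,500) carry a common
noise scale. The arm effects default to +0.001 QALYs and the implied cost
difference λ·0.001 − (−45) = £75, so the INMB mean is −£45 by
construction. The cost noise scale is solved in closed form so the derived
pairwise INMB SD equals the target exactly; an infeasible target (smaller
than the utility and covariate contributions alone) raises. Because every
ingredient is Gaussian, derived pairwise INMB is Gaussian: Shapiro–Wilk
does not reject normality in ≈95% of default-size cohorts (a test pins
≥90%).

Missingness applies to the 6- and 12-month utilities and the cost
components only, with logistic probability in (z, arm, z×arm) — MAR by
construction, since the drivers are fully observed — and intercepts
calibrated by quadrature so marginal rates hit their nominal values
(defaults 15%/25%/30%). The arm interaction makes complete-case analysis
biased, which is what the MI-recovery test exploits. What the generator
does **not** emulate: centre-level clustering, skewed cost distributions
(Gaussian components can go negative; accepted to keep INMB exactly
normal), dose arms, and non-uniform recruitment. Passing tests therefore
demonstrate the machinery under the stated Gaussian conditions, not
robustness to real-data pathologies.

## Operating-characteristics studies

The resampling engine draws bootstrap paths from a completed cohort's
pairwise INMB values: each path concatenates two with-replacement
resamples of the cohort and randomly orders them; a path at the cohort's
own size is the first half of its double-length construction (so the
half-length path of a given draw is a prefix of the full-length one).
The Gaussian simulation study solves a boundary per maximum sample size
on a grid (250–5,000) and simulates i.i.d. Normal(−45, 7,615²) streams,
5,000 replicates per setting by default, through a vectorised monitor
that is arithmetically identical to the trial engine (pinned by a
path-by-path equivalence test). Simulated paths use the same interim
schedule as the trial engine (first at 20, every 10, epochs with
n + τ < T_max). A reduced-replicate mode serves the routine test run;
the acceptance script uses the full 5,000.

At the default study conditions the exact solver gives: mean total sample
≈233 of 250 (71% of paths recruiting to the maximum), ≈585 of 1,000
(11%), and a plateau of ≈640 from T_max ≈ 2,000 onward (essentially no
path reaches maxima of 2,000+, since with an equivocal signal the
posterior mean almost surely crosses the late, tight boundary — which
decays like ~1/n, the free-boundary asymptote for this cost structure —
before recruitment completes). The expected-sample-size-to-maximum ratio
falls monotonically in T_max, and expected sample size under a six-month
follow-up (τ = 37, 7 interims) is below the twelve-month value at the
same maximum.

## Known limitations

* Known-σ_X updating only; a normal-gamma (unknown-variance) extension is
  out of scope.
* Covariate-adjusted estimation of E[INMB] (e.g. seemingly unrelated
  regressions) is not implemented; interim estimates are unadjusted
  between-arm comparisons.
* The QALY derivation (trapezoid over three assessments) and the cost
  component list are stand-ins for a full trial-specific economic
  analysis, isolated behind `derive_costs_and_qalys`.
* No discounting of costs or QALYs; no MNAR sensitivity analyses; no
  cluster-randomised extension.
* Money is represented as real pounds throughout; rounding only at
  reporting time.
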