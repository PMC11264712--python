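# Design constants of the main analysis (hand-osteoarthritis trial scale).
# All monetary amounts in pounds sterling at 2015 prices.
lambda_wtp: 30000.0       # maximum willingness to pay per QALY
annual_incidence: 2450.0  # patients affected per year
horizon_years: 10.0
P: 24500.0                # annual_incidence * horizon_years
I: 0.0                    # cost of switching technologies
c: 1650.0                 # variable research cost per pairwise allocation
fixed_cost_pre: 90216.0
fixed_cost_during: 204581.0
fixed_cost_post: 336042.0
delta_years: 1.0          # follow-up delay of the cost-effectiveness endpoint
recruit_rate: 74.0        # pairwise allocations per year
tau: 74                   # delay in pairwise allocations
T_max: 124
trial_days: 611.0
# prior on E[INMB]
mu0: 0.0
sigma_X: 7615.0
n0: 2.0
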