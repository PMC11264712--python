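"""Economic primitives: INMB arithmetic, QALY derivation, cost accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vbseq.econ_core import (DesignParams, PatientRecord, PriorSpec,
                             adoption_decision, compute_inmb, cost_accounting,
                             derive_costs_and_qalys, derive_params,
                             dump_config, load_config, pair_records,
                             read_records_csv, write_records_csv)


def _rec(arm, utils, costs, date=0.0, rid="r"):
    return PatientRecord(id=rid, arm=arm, rand_date=date,
                         utilities=list(utils), cost_components=list(costs))


class TestDeriveCostsAndQalys:
    @pytest.mark.parametrize("utils, costs, expected", [
        ((1.0, 1.0, 1.0), (0.0,), (0.0, 1.0)),
        ((0.5, 0.5, 0.5), (100.0, 50.0), (150.0, 0.5)),
        # trapezoid by hand: 0.25*0.8 + 0.5*0.6 + 0.25*0.4 = 0.6
        ((0.8, 0.6, 0.4), (0.0,), (0.0, 0.6)),
    ])
    def test_examples(self, utils, costs, expected):
        cost, qaly = derive_costs_and_qalys(_rec("N", utils, costs))
        assert cost == pytest.approx(expected[0])
        assert qaly == pytest.approx(expected[1])

    def test_missing_field_named(self):
        with pytest.raises(ValueError, match="u6"):
            derive_costs_and_qalys(_rec("N", (0.5, None, 0.5), (1.0,)))
        with pytest.raises(ValueError, match="cost_2"):
            derive_costs_and_qalys(_rec("N", (0.5, 0.5, 0.5), (1.0, None)))

    def test_out_of_range_utility_rejected(self):
        with pytest.raises(ValueError):
            PatientRecord(id="x", arm="N", rand_date=0.0,
                          utilities=[1.2, 0.5, 0.5], cost_components=[0.0])

    def test_half_year_window_scales_qalys(self):
        _, qaly = derive_costs_and_qalys(_rec("N", (1.0, 1.0, 1.0), (0.0,)),
                                         delta_years=0.5)
        assert qaly == pytest.approx(0.5)


class TestComputeInmb:
    def test_identical_outcomes_zero(self):
        pair = (_rec("N", (0.7, 0.7, 0.7), (500.0,)),
                _rec("S", (0.7, 0.7, 0.7), (500.0,)))
        assert compute_inmb(pair, 30_000.0) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # delta-QALY 0.01 at lambda 30,000, delta-cost 100 -> 200
        pair = (_rec("N", (0.71, 0.71, 0.71), (600.0,)),
                _rec("S", (0.70, 0.70, 0.70), (500.0,)))
        assert compute_inmb(pair, 30_000.0) == pytest.approx(200.0)

    def test_cheaper_new_technology_positive(self):
        # equal QALYs, new arm 39 pounds cheaper -> +39
        pair = (_rec("N", (0.7, 0.7, 0.7), (461.0,)),
                _rec("S", (0.7, 0.7, 0.7), (500.0,)))
        assert compute_inmb(pair, 30_000.0) == pytest.approx(39.0)

    def test_mismatched_arms_error(self):
        pair = (_rec("S", (0.7, 0.7, 0.7), (0.0,)),
                _rec("S", (0.7, 0.7, 0.7), (0.0,)))
        with pytest.raises(ValueError, match="arms"):
            compute_inmb(pair, 30_000.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
           st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
           st.floats(0.0, 5_000.0), st.floats(0.0, 5_000.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_under_arm_swap(self, u1, u2, c1, c2):
        a = compute_inmb((_rec("N", u1, (c1,)), _rec("S", u2, (c2,))), 30_000.0)
        b = compute_inmb((_rec("N", u2, (c2,)), _rec("S", u1, (c1,))), 30_000.0)
        assert a == pytest.approx(-b, abs=1e-6)


class TestAdoptionDecision:
    @pytest.mark.parametrize("mu, P, I, expected", [
        (-30.0, 24_500.0, 0.0, "keep_S"),
        (0.0, 24_500.0, 0.0, "keep_S"),  # tie resolves to the incumbent
        (1.0, 24_500.0, 0.0, "adopt_N"),
    ])
    def test_rule(self, mu, P, I, expected):
        assert adoption_decision(mu, P, I) == expected

    @given(st.floats(-1e5, 1e5), st.floats(1.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_zero_switch_cost_reduces_to_sign(self, mu, P):
        assert (adoption_decision(mu, P, 0.0) == "adopt_N") == (mu > 0)


class TestCostAccounting:
    def test_examples(self, params):
        assert cost_accounting(11, params)[0] == pytest.approx(18_150.0)
        assert cost_accounting(0, params)[0] == 0.0
        variable, total = cost_accounting(124, params)
        assert variable == pytest.approx(204_600.0)
        assert total == pytest.approx(204_600.0 + params.fixed_cost_total)

    def test_negative_count_error(self, params):
        with pytest.raises(ValueError):
            cost_accounting(-1, params)


class TestDeriveParams:
    def test_hero_like_derivation(self):
        p = derive_params(total_pairs=124, trial_days=611.0, delta_years=1.0,
                          variable_spend=204_581.0, annual_incidence=2_450.0,
                          horizon_years=10.0)
        assert p.tau == 74
        assert p.c == 1_650.0
        assert p.P == 24_500.0

    def test_tau_halves_with_delay(self):
        p1 = derive_params(total_pairs=124, trial_days=611.0, delta_years=1.0)
        p2 = derive_params(total_pairs=124, trial_days=611.0, delta_years=0.5,
                           T_max=124)
        assert p1.tau == 74 and p2.tau == 37

    def test_zero_duration_error(self):
        with pytest.raises(ValueError):
            derive_params(total_pairs=124, trial_days=0.0)


class TestExternalInterfaces:
    def test_record_csv_round_trip(self, tmp_path):
        recs = [_rec("N", (0.8, None, 0.4), (100.0, None), 5.0, "a"),
                _rec("S", (0.7, 0.6, 0.5), (90.0, 10.0), 7.0, "b")]
        recs[0].baseline_covariates = {"health_z": 0.3, "age_std": -1.0}
        recs[1].baseline_covariates = {"health_z": -0.2, "age_std": 0.4}
        path = tmp_path / "cohort.csv"
        write_records_csv(recs, path)
        back = read_records_csv(path)
        assert back[0].utilities[1] is None
        assert back[0].cost_components[1] is None
        assert back[1].utilities == [0.7, 0.6, 0.5]
        assert back[0].baseline_covariates["health_z"] == pytest.approx(0.3)

    def test_config_round_trip_and_validation(self, tmp_path, params, prior):
        path = tmp_path / "design.yaml"
        dump_config(params, prior, path)
        p2, pr2 = load_config(path)
        assert p2 == params and pr2 == prior
        path.write_text("sigma_X: 7615\ntau: 74\nT_max: 124\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            load_config(path)
        path.write_text("tau: 74\nT_max: 124\n")
        with pytest.raises(ValueError, match="sigma_X"):
            load_config(path)

    def test_pairing_by_arrival_rank_drops_surplus(self):
        recs = [_rec("N", (0.7, 0.7, 0.7), (0.0,), d, f"n{d}") for d in (3., 1.)]
        recs += [_rec("S", (0.7, 0.7, 0.7), (0.0,), d, f"s{d}")
                 for d in (2., 0.5, 9.)]
        pairs = pair_records(recs)
        assert len(pairs) == 2
        assert [p[0].id for p in pairs] == ["n1.0", "n3.0"]
        assert [p[1].id for p in pairs] == ["s0.5", "s2.0"]
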