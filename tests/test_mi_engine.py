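"""Sequential multiple imputation: identity, determinism, bias correction,
and the no-future-data-leak guarantee."""

import numpy as np
import pytest

from vbseq.econ_core import (PatientRecord, compute_inmb, pair_records,
                             records_to_frame)
from vbseq.mi_engine import (ImputationConfig, MISource, by_block_estimates,
                             impute_interim)
from vbseq.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="module")
def cohort_with_missing():
    return generate_cohort(GeneratorConfig(n_pairs=60, seed=11))


@pytest.fixture(scope="module")
def complete_cohort():
    return generate_cohort(GeneratorConfig(n_pairs=40, missing_rates={},
                                           seed=5))


class TestImputeInterim:
    def test_complete_data_identity(self, complete_cohort):
        """With no missing cells the m sets equal the input bit-for-bit."""
        completed = impute_interim(complete_cohort, ImputationConfig(seed=3))
        assert len(completed) == 5
        ref = records_to_frame(complete_cohort)
        for recset in completed:
            assert records_to_frame(recset).equals(ref)

    def test_observed_cells_untouched(self, cohort_with_missing):
        completed = impute_interim(cohort_with_missing,
                                   ImputationConfig(seed=3))
        df0 = records_to_frame(cohort_with_missing)
        cols = ["u6", "u12", "cost_1", "cost_2", "cost_3"]
        observed = ~df0[cols].isna()
        for recset in completed:
            df1 = records_to_frame(recset)
            assert ((df0[cols] == df1[cols]) | ~observed).all().all()
            assert not df1[cols].isna().any().any()

    def test_imputations_differ_across_m(self, cohort_with_missing):
        completed = impute_interim(cohort_with_missing,
                                   ImputationConfig(seed=3))
        a = records_to_frame(completed[0])
        b = records_to_frame(completed[1])
        assert not a.equals(b)

    def test_seed_determinism(self, cohort_with_missing):
        c1 = impute_interim(cohort_with_missing, ImputationConfig(seed=9))
        c2 = impute_interim(cohort_with_missing, ImputationConfig(seed=9))
        for r1, r2 in zip(c1, c2):
            assert records_to_frame(r1).equals(records_to_frame(r2))

    def test_sparsity_error_below_twenty_pairs(self):
        small = generate_cohort(GeneratorConfig(n_pairs=10, seed=2))
        with pytest.raises(ValueError, match="sparsity"):
            impute_interim(small, ImputationConfig())

    def test_entirely_missing_variable_named(self, complete_cohort):
        import copy
        broken = copy.deepcopy(complete_cohort)
        for r in broken:
            r.utilities[2] = None
        with pytest.raises(ValueError, match="u12"):
            impute_interim(broken, ImputationConfig(seed=0))

    def test_mi_beats_complete_case(self):
        """Pooled MI estimate is closer to the generator truth than the
        complete-case estimate, averaged over replicates."""
        reps = 100
        mi_err, cc_err = [], []
        for s in range(reps):
            cfg = GeneratorConfig(n_pairs=124, seed=3_000 + s)
            rec = generate_cohort(cfg)
            completed = impute_interim(
                rec, ImputationConfig(m=5, cycles=5, seed=6_000 + s))
            be = by_block_estimates(completed, 1, 124, cfg.lambda_wtp)
            mi_err.append(be.estimate - cfg.true_mean_inmb)
            xs = []
            for pr in pair_records(rec):
                try:
                    xs.append(compute_inmb(pr, cfg.lambda_wtp))
                except ValueError:
                    continue
            cc_err.append(np.mean(xs) - cfg.true_mean_inmb)
        assert abs(np.mean(mi_err)) < abs(np.mean(cc_err))


class TestByBlockEstimates:
    def test_complete_data_equals_direct_mean(self, complete_cohort):
        cfg = GeneratorConfig(n_pairs=40, missing_rates={}, seed=5)
        completed = impute_interim(complete_cohort, ImputationConfig(seed=0))
        be = by_block_estimates(completed, 11, 20, cfg.lambda_wtp)
        direct = np.mean([compute_inmb(pr, cfg.lambda_wtp)
                          for pr in pair_records(complete_cohort)[10:20]])
        assert be.estimate == pytest.approx(direct)
        assert be.between_var == 0.0

    def test_pooled_mean_is_average_of_block_means(self, cohort_with_missing):
        cfg = ImputationConfig(m=2, seed=4)
        completed = impute_interim(cohort_with_missing, cfg)
        be = by_block_estimates(completed, 21, 30, 30_000.0)
        per_imp = []
        for recset in completed:
            xs = [compute_inmb(pr, 30_000.0)
                  for pr in pair_records(recset)[20:30]]
            per_imp.append(np.mean(xs))
        assert be.estimate == pytest.approx(np.mean(per_imp))
        assert be.m_imputations == 2

    def test_empty_block_error(self, complete_cohort):
        completed = impute_interim(complete_cohort, ImputationConfig(seed=0))
        with pytest.raises(ValueError, match="empty"):
            by_block_estimates(completed, 5, 4, 30_000.0)


class TestMISource:
    def test_no_future_data_leak(self, cohort_with_missing):
        """Records randomised after the data cut never enter an interim."""
        src = MISource(cohort_with_missing, 30_000.0)
        cut = src._cut_date(20)
        avail = src._records_at_cut(cut)
        assert all(r.rand_date <= cut for r in avail)
        # sentinel: corrupt every record randomised after the cut
        import copy
        corrupted = copy.deepcopy(src.records)
        for r in corrupted:
            if r.rand_date > cut:
                r.utilities = [0.9, -0.5, -0.5]
                r.cost_components = [9e5] * len(r.cost_components)
        src2 = MISource(corrupted, 30_000.0, cfg=src.cfg)
        b1 = src.block_estimate(11, 20)
        b2 = src2.block_estimate(11, 20)
        assert b1.estimate == pytest.approx(b2.estimate)

    def test_partial_followup_masked(self, cohort_with_missing):
        src = MISource(cohort_with_missing, 30_000.0)
        cut = src._cut_date(20)
        for r in src._records_at_cut(cut):
            if r.rand_date + 365.0 > cut:
                assert r.utilities[2] is None
                assert all(c is None for c in r.cost_components)
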