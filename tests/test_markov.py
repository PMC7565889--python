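import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petct_cea import (
    BranchKind,
    BranchTarget,
    Conventions,
    MarkovState,
    ParameterSet,
    branch_outcome,
    build_transition_matrix,
    canonical_branch_config,
    convention_search,
    run_cohort,
)
from petct_cea.markov import PRINTED_BRANCH_TARGETS


def _quiet_params(**kw):
    """All transition probabilities zero unless overridden."""
    base = dict(
        p_recurrence=0.0,
        p_mets_timely=0.0,
        p_mets_delayed=0.0,
        p_death_recurrence_yr=0.0,
        p_remission_yr=0.0,
        discount_rate_yr=0.0,
    )
    base.update(kw)
    return ParameterSet(**base)


class TestTransitionMatrix:
    def test_zero_rates_give_identity(self, zero_mortality_table, conventions):
        config = canonical_branch_config(BranchKind.TN, _quiet_params(), conventions)
        P = build_transition_matrix(
            config, _quiet_params(), conventions, 68.0, zero_mortality_table
        )
        assert np.allclose(P, np.eye(4))

    def test_death_is_absorbing(self, params, conventions):
        config = canonical_branch_config(BranchKind.TP, params, conventions)
        P = build_transition_matrix(config, params, conventions, 68.0)
        assert np.array_equal(P[MarkovState.DEATH], [0, 0, 0, 1])

    def test_hepatic_death_annual_conversion(self, zero_mortality_table, params):
        conv = Conventions(death_recurrence_basis="annual", death_states="both")
        config = canonical_branch_config(BranchKind.TP, params, conv)
        P = build_transition_matrix(config, params, conv, 68.0, zero_mortality_table)
        expected = 1.0 - (1.0 - 0.0544) ** (1.0 / 12.0)  # ~0.004651
        assert P[MarkovState.HEPATIC_RECURRENCE, MarkovState.DEATH] == pytest.approx(
            expected, abs=1e-12
        )

    def test_inconsistent_conventions_raise_not_truncate(self, zero_mortality_table):
        # 0.5 + 0.6 of outgoing mass from NO_RECURRENCE cannot be per-cycle
        p = _quiet_params(p_recurrence=0.5, p_mets_timely=0.6)
        conv = Conventions(recurrence_basis="cycle", mets_basis="cycle")
        config = canonical_branch_config(BranchKind.TN, p, conv)
        with pytest.raises(ValueError, match="exceeds 1"):
            build_transition_matrix(config, p, conv, 68.0, zero_mortality_table)

    @given(
        rec=st.floats(0.0, 0.2),
        mets=st.floats(0.0, 0.3),
        death=st.floats(0.0, 0.3),
        remission=st.floats(0.0, 0.9),
        q=st.floats(0.0, 0.3),
        kind=st.sampled_from(list(BranchKind)),
    )
    @settings(max_examples=150, deadline=None)
    def test_rows_always_stochastic(self, rec, mets, death, remission, q, kind):
        from petct_cea import LifeTable

        p = ParameterSet(
            p_recurrence=rec,
            p_mets_timely=mets,
            p_mets_delayed=mets,
            p_death_recurrence_yr=death,
            p_remission_yr=remission,
        )
        conv = Conventions(remission_scope="both", death_states="both")
        table = LifeTable(ages=np.array([0.0]), q_annual=np.array([q]))
        config = canonical_branch_config(kind, p, conv)
        P = build_transition_matrix(config, p, conv, 68.0, table)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((P >= 0) & (P <= 1))


class TestRunCohort:
    def test_all_dead_cohort_accrues_nothing(self, params, conventions):
        from petct_cea import BranchConfig

        config = BranchConfig(
            kind=BranchKind.TN, initial_distribution=(0, 0, 0, 1), upfront_costs={}
        )
        trace = run_cohort(config, params, conventions)
        assert trace.cum_cost == 0.0
        assert trace.cum_qaly == 0.0
        assert trace.survival_at_horizon == 0.0

    def test_full_health_two_years_is_two_qalys(self, zero_mortality_table, conventions):
        p = _quiet_params()
        out = run_cohort(
            canonical_branch_config(BranchKind.TN, p, conventions),
            p,
            conventions,
            zero_mortality_table,
        )
        assert out.cum_qaly == pytest.approx(2.0, abs=1e-12)
        assert out.cum_cost == pytest.approx(p.cost_ct)

    def test_occupancy_conserved_every_cycle(self, params, conventions):
        for kind in BranchKind:
            trace = run_cohort(
                canonical_branch_config(kind, params, conventions), params, conventions
            )
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(trace.survival) <= 1e-12)

    def test_zero_discount_matches_hand_summed_three_cycle_toy(
        self, zero_mortality_table
    ):
        # NO->HEPATIC at 0.5/cycle, nothing else moves; utilities 1 and 0.65
        p = _quiet_params(p_recurrence=0.5, horizon_months=3)
        conv = Conventions(mets_from_hepatic=False, first_cycle_utility=False)
        trace = run_cohort(
            canonical_branch_config(BranchKind.TN, p, conv),
            p,
            conv,
            zero_mortality_table,
        )
        # occupancy (N, H): (1,0) -> (.5,.5) -> (.25,.75)
        expected = (1.0 + (0.5 + 0.5 * 0.65) + (0.25 + 0.75 * 0.65)) / 12.0
        assert trace.cum_qaly == pytest.approx(expected, abs=1e-12)

    def test_raising_utility_never_decreases_qalys(self, params, conventions):
        lo = branch_outcome(BranchKind.TN, params.replace(u_other_recurrence=0.19), conventions)
        hi = branch_outcome(BranchKind.TN, params.replace(u_other_recurrence=0.30), conventions)
        assert hi.qaly >= lo.qaly

    def test_raising_costs_never_decreases_cost(self, params, conventions):
        for field in ("cost_cancer_yearly", "cost_reablation_total", "cost_ct"):
            hi = branch_outcome(
                BranchKind.FP, params.replace(**{field: getattr(params, field) * 1.5}),
                conventions,
            )
            lo = branch_outcome(BranchKind.FP, params, conventions)
            assert hi.cost >= lo.cost

    def test_raising_disease_mortality_never_increases_survival(self, params, conventions):
        hi = branch_outcome(
            BranchKind.FN, params.replace(p_death_recurrence_yr=0.2), conventions
        )
        lo = branch_outcome(BranchKind.FN, params, conventions)
        assert hi.survival <= lo.survival

    def test_trace_export_round_trip(self, params, conventions, tmp_path):
        trace = run_cohort(
            canonical_branch_config(BranchKind.TP, params, conventions), params, conventions
        )
        frame = trace.to_frame()
        path = tmp_path / "trace.csv"
        frame.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert np.allclose(back["cum_cost"].iloc[-1], trace.cum_cost)
        assert np.allclose(back["cum_qaly"].iloc[-1], trace.cum_qaly)


class TestBranchOutcomes:
    def test_fp_costs_exactly_one_reablation_more_than_tn(self, params, conventions):
        tn = branch_outcome(BranchKind.TN, params, conventions)
        fp = branch_outcome(BranchKind.FP, params, conventions)
        assert fp.cost - tn.cost == pytest.approx(params.cost_reablation_total, abs=1e-9)
        assert fp.qaly == pytest.approx(tn.qaly, abs=1e-12)
        assert fp.survival == pytest.approx(tn.survival, abs=1e-12)

    def test_fn_is_costlier_and_worse_than_tp(self, params, conventions):
        tp = branch_outcome(BranchKind.TP, params, conventions)
        fn = branch_outcome(BranchKind.FN, params, conventions)
        assert fn.cost > tp.cost
        assert fn.qaly < tp.qaly


class TestConventionSearch:
    def test_single_candidate_grid(self, params, conventions):
        ranked = convention_search(params, PRINTED_BRANCH_TARGETS, [conventions])
        assert len(ranked) == 1
        assert ranked[0][0] == conventions
        assert ranked[0][1] >= 0.0

    def test_empty_grid_rejected(self, params):
        with pytest.raises(ValueError):
            convention_search(params, PRINTED_BRANCH_TARGETS, [])

    def test_self_consistency_round_trip(self, params):
        # targets generated from a known convention rank it first with ~0 score
        truth = Conventions(fn_delay_cycles=4, mets_basis="annual")
        targets = tuple(
            BranchTarget(k, *(lambda o: (o.cost, o.qaly, o.survival))(
                branch_outcome(k, params, truth)
            ))
            for k in BranchKind
        )
        grid = [
            truth,
            Conventions(fn_delay_cycles=2, mets_basis="annual"),
            Conventions(fn_delay_cycles=4, mets_basis="cycle"),
            Conventions(),
        ]
        ranked = convention_search(params, targets, grid)
        assert ranked[0][0] == truth
        assert ranked[0][1] == pytest.approx(0.0, abs=1e-16)

    def test_ties_break_lexicographically(self, params):
        # two conventions differing only in a field that cannot affect the
        # outcome (remission basis while remission is off) tie exactly
        a = Conventions(remission_scope="none", remission_basis="annual")
        b = Conventions(remission_scope="none", remission_basis="cycle")
        ranked = convention_search(params, PRINTED_BRANCH_TARGETS, [b, a])
        assert ranked[0][1] == ranked[1][1]
        assert ranked[0][0].encoding() < ranked[1][0].encoding()


def test_infeasible_conventions_rank_last_not_crash(params):
    # remission 80% per cycle plus per-cycle mets and death overflows the
    # hepatic row; the search must rank such candidates last, not abort
    infeasible = Conventions(
        remission_basis="cycle",
        remission_scope="both",
        death_recurrence_basis="cycle",
        death_states="both",
    )
    ranked = convention_search(
        params, PRINTED_BRANCH_TARGETS, [infeasible, Conventions()]
    )
    assert ranked[0][0] == Conventions()
    assert ranked[1][1] == float("inf")
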