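import numpy as np
import pytest

from petct_cea import (
    BranchKind,
    MarkovState,
    ParameterSet,
    branch_outcome,
    classify_test_outcomes,
    export_synthetic_dataset,
    load_synthetic_dataset,
    simulate_branch,
    simulate_cohort,
    simulate_patient,
    strategy_outcome,
    summarize_trajectories,
)


def _quiet_params(**kw):
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


class TestSimulatePatient:
    def test_no_transitions_patient_stays_put(self, zero_mortality_table, conventions):
        p = _quiet_params()
        rng = np.random.default_rng(0)
        traj = simulate_patient(BranchKind.TN, p, conventions, rng, zero_mortality_table)
        assert all(s == MarkovState.NO_RECURRENCE for s in traj.states)
        assert traj.death_cycle is None

    def test_certain_reablation_success_starts_healthy(self, params, conventions):
        p = params.replace(p_reablation_success=1.0)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            traj = simulate_patient(BranchKind.TP, p, conventions, rng)
            assert traj.states[0] == MarkovState.NO_RECURRENCE

    def test_healthy_undiscounted_trajectory_accrues_two_qalys(
        self, zero_mortality_table, conventions
    ):
        p = _quiet_params()
        traj = simulate_patient(
            BranchKind.TN, p, conventions, np.random.default_rng(1), zero_mortality_table
        )
        assert traj.qaly == pytest.approx(2.0, abs=1e-12)


class TestSimulateCohort:
    def test_single_patient_summary_equals_trajectory(self, params, conventions):
        summary, trajectories = simulate_cohort(
            1, 5, "CE-CT", params, conventions, return_trajectories=True
        )
        assert summary.n == 1
        assert summary.mean_cost == pytest.approx(trajectories[0].cost)
        assert summary.mean_qaly == pytest.approx(trajectories[0].qaly)

    def test_zero_patients_rejected(self, params, conventions):
        with pytest.raises(ValueError):
            simulate_cohort(0, 1, "CE-CT", params, conventions)

    def test_growing_n_never_reshuffles_earlier_patients(self, params, conventions):
        _, small = simulate_cohort(5, 3, "PET/CT", params, conventions, return_trajectories=True)
        _, large = simulate_cohort(9, 3, "PET/CT", params, conventions, return_trajectories=True)
        for a, b in zip(small, large):
            assert a == b

    def test_branch_fractions_match_test_accuracy(self, params, conventions):
        n = 6000
        summary = simulate_cohort(n, 11, "CE-CT", params, conventions)
        weights = classify_test_outcomes(
            params.p_incomplete_ablation, params.sens_ct, params.spec_ct
        ).as_dict()
        for kind, w in weights.items():
            se = np.sqrt(w * (1 - w) / n)
            assert abs(summary.branch_counts[kind] / n - w) < 3 * se

    def test_cohort_mean_matches_strategy_outcome(self, params, conventions):
        n = 4000
        summary = simulate_cohort(n, 13, "CE-CT", params, conventions)
        expected = strategy_outcome("CE-CT", params, conventions)
        assert abs(summary.mean_cost - expected.cost) < 3 * summary.se_cost
        assert abs(summary.mean_qaly - expected.qaly) < 3 * summary.se_qaly


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind", list(BranchKind))
    def test_branch_means_within_three_se_of_cohort(self, kind, params, conventions):
        trajectories = simulate_branch(3000, 17, kind, params, conventions)
        s = summarize_trajectories(trajectories)
        o = branch_outcome(kind, params, conventions)
        assert abs(s.mean_cost - o.cost) < 3 * s.se_cost
        assert abs(s.mean_qaly - o.qaly) < 3 * s.se_qaly
        assert abs(s.survival - o.survival) < 3 * max(s.se_survival, 1e-9)

    def test_kaplan_meier_survival_matches_cohort_curve(self, params, conventions):
        from petct_cea import canonical_branch_config, run_cohort

        n = 3000
        trajectories = simulate_branch(n, 19, BranchKind.TN, params, conventions)
        trace = run_cohort(
            canonical_branch_config(BranchKind.TN, params, conventions), params, conventions
        )
        alive = np.array(
            [[s != MarkovState.DEATH for s in t.states] for t in trajectories]
        ).mean(axis=0)
        for t, (emp, exp) in enumerate(zip(alive, trace.survival)):
            se = np.sqrt(max(exp * (1 - exp), 1e-12) / n)
            assert abs(emp - exp) <= 3 * se + 1e-9, f"cycle {t}"


class TestExport:
    def test_round_trip_identical_trajectories(self, params, conventions, tmp_path):
        _, trajectories = simulate_cohort(
            10, 23, "CE-CT", params, conventions, return_trajectories=True
        )
        path = tmp_path / "traj.csv"
        export_synthetic_dataset(trajectories, path)
        back = load_synthetic_dataset(path)
        assert back == trajectories

    def test_file_has_one_record_block_per_patient(self, params, conventions, tmp_path):
        _, trajectories = simulate_cohort(
            10, 29, "CE-CT", params, conventions, return_trajectories=True
        )
        path = tmp_path / "traj.csv"
        export_synthetic_dataset(trajectories, path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert frame["patient_id"].nunique() == 10
        assert len(frame) == 10 * (params.n_cycles + 1)

    def test_summary_recomputed_from_file_matches_in_memory(
        self, params, conventions, tmp_path
    ):
        summary, trajectories = simulate_cohort(
            50, 31, "PET/CT", params, conventions, return_trajectories=True
        )
        path = tmp_path / "traj.csv"
        export_synthetic_dataset(trajectories, path)
        reloaded = summarize_trajectories(load_synthetic_dataset(path), seed=summary.seed)
        assert reloaded.mean_cost == pytest.approx(summary.mean_cost)
        assert reloaded.mean_qaly == pytest.approx(summary.mean_qaly)
        assert reloaded.survival == pytest.approx(summary.survival)
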