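"""Patient-level microsimulation twin of the cohort engine.

Individual trajectories are sampled cycle by cycle from the same transition
matrices, cost and utility accrual rules as :func:`petct_cea.markov.run_cohort`,
so cohort expectations can be validated by Monte-Carlo convergence (first-order
microsimulation).  Per-patient random substreams are derived from the master
seed, so enlarging ``n`` never reshuffles earlier patients.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .decision import classify_test_outcomes, _modality_accuracy
from .markov import (
    CALIBRATED_CONVENTIONS,
    BranchConfig,
    BranchKind,
    Conventions,
    MarkovState,
    build_transition_matrix,
    canonical_branch_config,
)
from .parameters import LifeTable, ParameterSet, default_life_table

__all__ = [
    "PatientTrajectory",
    "MicrosimSummary",
    "simulate_patient",
    "simulate_branch",
    "simulate_cohort",
    "summarize_trajectories",
    "export_synthetic_dataset",
    "load_synthetic_dataset",
]


@dataclass(frozen=True)
class PatientTrajectory:
    """One simulated patient: per-cycle states and discounted accruals."""

    patient_id: int
    kind: BranchKind
    states: tuple  # state at each cycle boundary, length n_cycles + 1
    cost_increments: tuple
    qaly_increments: tuple

    @property
    def cost(self) -> float:
        return float(sum(self.cost_increments))

    @property
    def qaly(self) -> float:
        return float(sum(self.qaly_increments))

    @property
    def alive_at_horizon(self) -> bool:
        return self.states[-1] != MarkovState.DEATH

    @property
    def death_cycle(self) -> Optional[int]:
        """First cycle boundary in DEATH, or None if censored at horizon."""
        for t, s in enumerate(self.states):
            if s == MarkovState.DEATH:
                return t
        return None


@dataclass(frozen=True)
class MicrosimSummary:
    """Monte-Carlo means and standard errors, per branch and overall."""

    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    survival: float
    se_survival: float
    branch_counts: dict
    branch_means: dict  # kind -> (mean_cost, mean_qaly, survival)


def _patient_rng(seed: int, patient_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(patient_id)]))


def simulate_patient(
    branch: BranchKind,
    params: ParameterSet,
    conventions: Conventions = CALIBRATED_CONVENTIONS,
    rng: Optional[np.random.Generator] = None,
    life_table: Optional[LifeTable] = None,
    patient_id: int = 0,
) -> PatientTrajectory:
    """Sample one trajectory under the canonical branch configuration."""
    if rng is None:
        rng = np.random.default_rng()
    table = life_table if life_table is not None else default_life_table()
    config = canonical_branch_config(branch, params, conventions)
    n = params.n_cycles
    cm = params.cycle_months
    year_frac = cm / 12.0
    utilities = (
        params.u_no_recurrence,
        params.u_hepatic_recurrence,
        params.u_other_recurrence,
        params.u_death,
    )
    state_cost_yr = (
        params.cost_no_cancer_yearly,
        params.cost_cancer_yearly,
        params.cost_cancer_yearly,
        0.0,
    )

    init = np.asarray(config.initial_distribution)
    state = int(rng.choice(4, p=init))
    states = [state]
    cost_inc: list[float] = []
    qaly_inc: list[float] = []
    matrix_cache: dict[int, np.ndarray] = {}
    uniforms = rng.random(n)

    for t in range(n):
        months = t * cm
        years = months / 12.0
        if conventions.discount_granularity == "year":
            years = float(int(years))
        disc = (1.0 + params.discount_rate_yr) ** (-years)

        event_cost = 0.0
        reablated = False
        if config.reablation_cycle is not None and t == config.reablation_cycle:
            scope = conventions.fn_cost_scope
            in_hepatic = state == MarkovState.HEPATIC_RECURRENCE
            if (
                (scope == "hepatic" and in_hepatic)
                or (scope == "alive" and state != MarkovState.DEATH)
                or scope == "cohort"
            ):
                event_cost += config.reablation_cost
            if in_hepatic:
                reablated = True
                if rng.random() < params.p_reablation_success:
                    state = int(MarkovState.NO_RECURRENCE)
        event_cost += config.upfront_costs.get(t, 0.0)
        states[-1] = state  # record post-event state at this boundary

        age_idx = int(np.floor(params.start_age_years + t * year_frac))
        P = matrix_cache.get(age_idx)
        if P is None:
            P = build_transition_matrix(
                config, params, conventions, params.start_age_years + t * year_frac, table
            )
            matrix_cache[age_idx] = P
        row = np.cumsum(P[state])
        next_state = int(min(np.searchsorted(row, uniforms[t], side="right"), 3))

        event_cycle = (
            config.reablation_cycle is not None and t == config.reablation_cycle
        )
        half = conventions.half_cycle and not event_cycle
        if t == 0 and conventions.first_cycle_utility:
            util = params.u_first_month if state != MarkovState.DEATH else 0.0
        elif reablated:
            util = params.u_first_month
        elif half:
            util = 0.5 * (utilities[state] + utilities[next_state])
        elif event_cycle:
            util = utilities[state]
        else:
            util = utilities[state]
        state_cost = (
            0.5 * (state_cost_yr[state] + state_cost_yr[next_state])
            if conventions.half_cycle
            else state_cost_yr[state]
        )
        qaly_inc.append(util * year_frac * disc)
        cost_inc.append((state_cost * year_frac + event_cost) * disc)

        state = next_state
        states.append(state)

    return PatientTrajectory(
        patient_id, BranchKind(branch), tuple(states), tuple(cost_inc), tuple(qaly_inc)
    )


def _classify_patient(
    rng: np.random.Generator, prevalence: float, sens: float, spec: float
) -> BranchKind:
    diseased = rng.random() < prevalence
    if diseased:
        return BranchKind.TP if rng.random() < sens else BranchKind.FN
    return BranchKind.TN if rng.random() < spec else BranchKind.FP


def simulate_branch(
    n: int,
    seed: int,
    branch: BranchKind,
    params: ParameterSet,
    conventions: Conventions = CALIBRATED_CONVENTIONS,
    life_table: Optional[LifeTable] = None,
) -> list[PatientTrajectory]:
    """Simulate ``n`` patients of a fixed diagnostic classification."""
    if n < 1:
        raise ValueError("n must be >= 1")
    table = life_table if life_table is not None else default_life_table()
    return [
        simulate_patient(
            branch, params, conventions, _patient_rng(seed, i), table, patient_id=i
        )
        for i in range(n)
    ]


def simulate_cohort(
    n: int,
    seed: int,
    strategy: str,
    params: ParameterSet,
    conventions: Conventions = CALIBRATED_CONVENTIONS,
    life_table: Optional[LifeTable] = None,
    return_trajectories: bool = False,
):
    """Simulate ``n`` patients under a follow-up strategy.

    Each patient is first classified TP/FN/TN/FP by Bernoulli draws from
    prevalence and the strategy's sensitivity/specificity, then simulated
    through the Markov process.  The strategy-level scan-cost differential
    (PET/CT price minus the embedded CE-CT scan) is added per patient.
    Returns a :class:`MicrosimSummary` (and the trajectories if requested).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    table = life_table if life_table is not None else default_life_table()
    sens, spec = _modality_accuracy(strategy, params)
    scan_extra = (params.cost_pet - params.cost_ct) if strategy == "PET/CT" else 0.0
    prevalence = params.p_incomplete_ablation

    trajectories: list[PatientTrajectory] = []
    for i in range(n):
        rng = _patient_rng(seed, i)
        kind = _classify_patient(rng, prevalence, sens, spec)
        traj = simulate_patient(kind, params, conventions, rng, table, patient_id=i)
        if scan_extra:
            inc = list(traj.cost_increments)
            inc[0] += scan_extra
            traj = PatientTrajectory(
                traj.patient_id, traj.kind, traj.states, tuple(inc), traj.qaly_increments
            )
        trajectories.append(traj)
    summary = summarize_trajectories(trajectories, seed=seed)
    if return_trajectories:
        return summary, trajectories
    return summary


def summarize_trajectories(
    trajectories: Sequence[PatientTrajectory], seed: int = 0
) -> MicrosimSummary:
    """Means and Monte-Carlo standard errors over a trajectory set."""
    if not trajectories:
        raise ValueError("no trajectories to summarize")
    n = len(trajectories)
    costs = np.array([t.cost for t in trajectories])
    qalys = np.array([t.qaly for t in trajectories])
    alive = np.array([t.alive_at_horizon for t in trajectories], dtype=float)

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    branch_counts: dict = {}
    branch_means: dict = {}
    for kind in BranchKind:
        mask = np.array([t.kind == kind for t in trajectories])
        branch_counts[kind] = int(mask.sum())
        if mask.any():
            branch_means[kind] = (
                float(costs[mask].mean()),
                float(qalys[mask].mean()),
                float(alive[mask].mean()),
            )
    return MicrosimSummary(
        n=n,
        seed=seed,
        mean_cost=float(costs.mean()),
        se_cost=se(costs),
        mean_qaly=float(qalys.mean()),
        se_qaly=se(qalys),
        survival=float(alive.mean()),
        se_survival=se(alive),
        branch_counts=branch_counts,
        branch_means=branch_means,
    )


_EXPORT_HEADER = (
    "patient_id",
    "branch",
    "cycle",
    "state",
    "cost_increment",
    "qaly_increment",
)


def export_synthetic_dataset(
    trajectories: Sequence[PatientTrajectory], path
) -> None:
    """Write one CSV row per patient-cycle boundary (full float precision).

    The terminal boundary (cycle == horizon) is written with zero increments
    so trajectories round-trip exactly through :func:`load_synthetic_dataset`.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EXPORT_HEADER)
        for traj in trajectories:
            n = len(traj.cost_increments)
            for t in range(n + 1):
                writer.writerow(
                    [
                        traj.patient_id,
                        traj.kind.value,
                        t,
                        MarkovState(traj.states[t]).name,
                        repr(traj.cost_increments[t]) if t < n else "0.0",
                        repr(traj.qaly_increments[t]) if t < n else "0.0",
                    ]
                )


def load_synthetic_dataset(path) -> list[PatientTrajectory]:
    """Re-read an exported trajectory table (inverse of export)."""
    by_patient: dict[int, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pid = int(row["patient_id"])
            rec = by_patient.setdefault(
                pid,
                {"kind": BranchKind(row["branch"]), "states": [], "cost": [], "qaly": []},
            )
            rec["states"].append(int(MarkovState[row["state"]]))
            rec["cost"].append(float(row["cost_increment"]))
            rec["qaly"].append(float(row["qaly_increment"]))
    out = []
    for pid in sorted(by_patient):
        rec = by_patient[pid]
        out.append(
            PatientTrajectory(
                pid,
                rec["kind"],
                tuple(rec["states"]),
                tuple(rec["cost"][:-1]),  # terminal boundary row carries no accrual
                tuple(rec["qaly"][:-1]),
            )
        )
    return out
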