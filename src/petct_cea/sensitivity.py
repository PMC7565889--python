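"""Deterministic and probabilistic sensitivity analyses.

One-way (tornado) sweeps recompute both strategies and the ICER over a
parameter range; threshold analysis bisects for the parameter value at which
the ICER crosses the willingness-to-pay; probabilistic sensitivity analysis
(PSA) re-runs the model with beta/gamma-sampled inputs and summarises the
result as a cost-effectiveness acceptability curve (CEAC) via net monetary
benefit NMB = WTP * E - C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .decision import StrategyResult, icer, strategy_outcome
from .markov import CALIBRATED_CONVENTIONS, Conventions
from .parameters import (
    DistributionSpec,
    LifeTable,
    ParameterSet,
    default_distribution_specs,
)

__all__ = [
    "TornadoEntry",
    "PsaResult",
    "CeacPoint",
    "NoCrossingError",
    "one_way_sweep",
    "tornado",
    "threshold_find",
    "run_psa",
    "ceac",
]

#: parameters swept in the published tornado diagram
TORNADO_PARAMS = ("cost_ct", "cost_pet", "sens_ct", "spec_ct", "sens_pet", "spec_pet")

_PROB_PARAMS = frozenset(
    {
        "p_incomplete_ablation",
        "sens_ct",
        "spec_ct",
        "sens_pet",
        "spec_pet",
        "u_first_month",
        "u_no_recurrence",
        "u_hepatic_recurrence",
        "u_other_recurrence",
        "u_death",
        "p_reablation_success",
        "p_recurrence",
        "p_mets_timely",
        "p_mets_delayed",
        "p_death_recurrence_yr",
        "p_remission_yr",
    }
)


class NoCrossingError(RuntimeError):
    """The ICER does not cross the willingness-to-pay over the bracket."""


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of a tornado diagram."""

    parameter: str
    low: float
    high: float
    icer_low: Optional[float]
    icer_high: Optional[float]
    icer_base: Optional[float]
    icer_values: tuple  # ICER at every grid point (None where dominated)

    @property
    def span(self) -> float:
        """Width of the bar around the base-case expected value."""
        finite = [v for v in self.icer_values if v is not None]
        if not finite:
            return 0.0
        return max(finite) - min(finite)


def _icer_at(
    params: ParameterSet,
    conventions: Conventions,
    life_table: Optional[LifeTable],
) -> tuple[Optional[float], StrategyResult, StrategyResult]:
    ct = strategy_outcome("CE-CT", params, conventions, life_table)
    pet = strategy_outcome("PET/CT", params, conventions, life_table)
    return icer(ct, pet).icer, ct, pet


def _clamped(params: ParameterSet, name: str, value: float) -> ParameterSet:
    if name in _PROB_PARAMS and not (0.0 <= value <= 1.0):
        clamped = min(max(value, 0.0), 1.0)
        warnings.warn(
            f"sweep value {value!r} for {name} clamped to {clamped}", stacklevel=3
        )
        value = clamped
    return params.replace(**{name: value})


def one_way_sweep(
    param: str,
    low: float,
    high: float,
    n_points: int = 2,
    params: Optional[ParameterSet] = None,
    conventions: Conventions = CALIBRATED_CONVENTIONS,
    life_table: Optional[LifeTable] = None,
) -> TornadoEntry:
    """Recompute the ICER of PET/CT vs CE-CT over a one-parameter range."""
    if params is None:
        params = ParameterSet()
    if low > high:
        raise ValueError("low must not exceed high")
    n_points = max(int(n_points), 1)
    grid = np.linspace(low, high, n_points) if low < high else np.array([low])
    values = tuple(
        _icer_at(_clamped(params, param, float(x)), conventions, life_table)[0]
        for x in grid
    )
    base_icer = _icer_at(params, conventions, life_table)[0]
    return TornadoEntry(
        parameter=param,
        low=float(grid[0]),
        high=float(grid[-1]),
        icer_low=values[0],
        icer_high=values[-1],
        icer_base=base_icer,
        icer_values=values,
    )


def tornado(
    params: Optional[ParameterSet] = None,
    conventions: Conventions = CALIBRATED_CONVENTIONS,
    rel_range: float = 0.20,
    parameters: Sequence[str] = TORNADO_PARAMS,
    n_points: int = 2,
    life_table: Optional[LifeTable] = None,
) -> list[TornadoEntry]:
    """One-way sweeps of each diagnostic parameter over +/- ``rel_range``."""
    if params is None:
        params = ParameterSet()
    entries = []
    for name in parameters:
        base = getattr(params, name)
        low, high = base * (1.0 - rel_range), base * (1.0 + rel_range)
        if name in _PROB_PARAMS:
            low, high = max(low, 0.0), min(high, 1.0)
        entries.append(
            one_way_sweep(name, low, high, n_points, params, conventions, life_table)
        )
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def threshold_find(
    param: str,
    wtp: float,
    bracket: tuple[float, float],
    tol: float = 1e-4,
    params: Optional[ParameterSet] = None,
    conventions: Conventions = CALIBRATED_CONVENTIONS,
    life_table: Optional[LifeTable] = None,
) -> float:
    """Bisect for the parameter value where the ICER equals ``wtp``.

    Raises :class:`NoCrossingError` if ``ICER - wtp`` keeps its sign over the
    bracket.  Dominant strategies count as below any positive threshold and
    dominated ones as above it, so the crossing is well defined even when the
    ICER is undefined at one end of the bracket.
    """
    if params is None:
        params = ParameterSet()
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy low < high")

    def objective(x: float) -> float:
        p = _clamped(params, param, x)
        value, ct, pet = _icer_at(p, conventions, life_table)
        if value is None:
            from .decision import icer as _icer

            res = _icer(ct, pet)
            return -wtp if res.dominance == "dominant" else wtp
        return value - wtp

    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoCrossingError(
            f"ICER - wtp does not change sign over [{lo}, {hi}] for {param}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = objective(mid)
        if f_mid == 0.0:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class PsaResult:
    """Per-iteration PSA draws and strategy outcomes."""

    seed: int
    n_iter: int
    cost_ct: np.ndarray
    qaly_ct: np.ndarray
    cost_pet: np.ndarray
    qaly_pet: np.ndarray

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_pet - self.cost_ct

    @property
    def delta_effect(self) -> np.ndarray:
        return self.qaly_pet - self.qaly_ct

    def fraction_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations in which PET/CT has the higher net
        monetary benefit at ``wtp`` (ties count as not cost-effective)."""
        nmb_pet = wtp * self.qaly_pet - self.cost_pet
        nmb_ct = wtp * self.qaly_ct - self.cost_ct
        return float(np.mean(nmb_pet > nmb_ct))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iter),
                "cost_ct": self.cost_ct,
                "qaly_ct": self.qaly_ct,
                "cost_pet": self.cost_pet,
                "qaly_pet": self.qaly_pet,
                "delta_cost": self.delta_cost,
                "delta_effect": self.delta_effect,
            }
        )


@dataclass(frozen=True)
class CeacPoint:
    wtp: float
    fraction_cost_effective: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_cost_effective <= 1.0):
            raise ValueError("fraction_cost_effective must lie in [0, 1]")


def run_psa(
    n_iter: int = 30_000,
    seed: int = 0,
    dist_specs: Optional[Sequence[DistributionSpec]] = None,
    params: Optional[ParameterSet] = None,
    conventions: Conventions = CALIBRATED_CONVENTIONS,
    life_table: Optional[LifeTable] = None,
) -> PsaResult:
    """Probabilistic sensitivity analysis.

    Each iteration draws every uncertain parameter independently from its
    beta/gamma distribution (method of moments), re-runs both strategies and
    records outcomes.  Deterministic given ``seed`` (numpy PCG64 generator).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if params is None:
        params = ParameterSet()
    if dist_specs is None:
        dist_specs = default_distribution_specs(params)
    rng = np.random.default_rng(seed)
    draws = {spec.name: spec.sample(rng, n_iter) for spec in dist_specs}

    cost_ct = np.empty(n_iter)
    qaly_ct = np.empty(n_iter)
    cost_pet = np.empty(n_iter)
    qaly_pet = np.empty(n_iter)
    from .markov import BranchKind, branch_outcome

    for i in range(n_iter):
        p_i = params.replace(**{k: float(v[i]) for k, v in draws.items()})
        outcomes = {
            kind: branch_outcome(kind, p_i, conventions, life_table)
            for kind in BranchKind
        }
        ct = strategy_outcome(
            "CE-CT", p_i, conventions, life_table, branch_outcomes=outcomes
        )
        pet = strategy_outcome(
            "PET/CT", p_i, conventions, life_table, branch_outcomes=outcomes
        )
        cost_ct[i], qaly_ct[i] = ct.cost, ct.qaly
        cost_pet[i], qaly_pet[i] = pet.cost, pet.qaly
    return PsaResult(seed, n_iter, cost_ct, qaly_ct, cost_pet, qaly_pet)


def default_wtp_grid() -> np.ndarray:
    """0 to 200,000 USD/QALY in steps of 5,000."""
    return np.arange(0.0, 200_001.0, 5_000.0)


def ceac(psa: PsaResult, wtp_grid: Sequence[float]) -> list[CeacPoint]:
    """Cost-effectiveness acceptability curve of PET/CT over a WTP grid."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must not be empty")
    return [
        CeacPoint(float(w), psa.fraction_cost_effective(float(w))) for w in wtp_grid
    ]
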