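"""Diagnostic-strategy layer: branch weights, expected outcomes, ICER.

A follow-up scan classifies each patient into one of four branches (true/
false positive/negative) according to the prevalence of incomplete ablation
and the scan's sensitivity/specificity.  A strategy's expected cost and
QALYs are the branch-weighted averages of the Markov branch outcomes, plus
the strategy's scan-cost convention; strategies are compared by the
incremental cost-effectiveness ratio (C1 - C0) / (E1 - E0), computed on
unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .markov import (
    CALIBRATED_CONVENTIONS,
    BranchKind,
    BranchOutcome,
    Conventions,
    branch_outcome,
)
from .parameters import LifeTable, ParameterSet, ParameterValidationError

__all__ = [
    "BranchWeights",
    "StrategyResult",
    "IcerResult",
    "MODALITIES",
    "PUBLISHED_STRATEGY_RESULTS",
    "PUBLISHED_ICER",
    "classify_test_outcomes",
    "strategy_outcome",
    "icer",
    "published_branch_outcomes",
]

MODALITIES = ("CE-CT", "PET/CT")

#: Published base-case strategy outcomes (total cost USD, QALYs) and ICER,
#: used as validation targets for the decision-layer aggregation.
PUBLISHED_STRATEGY_RESULTS = {"CE-CT": (28_625.08, 0.755), "PET/CT": (29_239.97, 0.767)}
PUBLISHED_ICER = 50_338.96

#: Scan-cost conventions.  "embedded_index_ct": every branch outcome already
#: carries one index CE-CT scan, so only the PET/CT price differential is
#: added at the strategy level (reproduces the published totals).
#: "full_scan": branch outcomes are taken net of any scan and the full
#: modality price is added per strategy.
COST_CONVENTIONS = ("embedded_index_ct", "full_scan")


@dataclass(frozen=True)
class BranchWeights:
    """Probabilities of the four diagnostic classifications."""

    p_tp: float
    p_fn: float
    p_tn: float
    p_fp: float

    def __post_init__(self) -> None:
        total = self.p_tp + self.p_fn + self.p_tn + self.p_fp
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"branch weights must sum to 1, got {total!r}")

    def as_dict(self) -> dict:
        return {
            BranchKind.TP: self.p_tp,
            BranchKind.FN: self.p_fn,
            BranchKind.TN: self.p_tn,
            BranchKind.FP: self.p_fp,
        }


@dataclass(frozen=True)
class StrategyResult:
    modality: str
    cost: float  # expected discounted cost, USD
    qaly: float  # expected discounted QALYs


@dataclass(frozen=True)
class IcerResult:
    """Incremental comparison of a comparator against a reference strategy."""

    delta_cost: float
    delta_effect: float
    icer: Optional[float]  # USD/QALY; None off the trade-off quadrants
    dominance: str  # "tradeoff" | "dominant" | "dominated" | "undefined"


def classify_test_outcomes(
    prevalence: float, sensitivity: float, specificity: float
) -> BranchWeights:
    """Branch weights from disease prevalence and test accuracy."""
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not (0.0 <= v <= 1.0):
            raise ParameterValidationError(f"{name} must lie in [0, 1], got {v!r}")
    return BranchWeights(
        p_tp=prevalence * sensitivity,
        p_fn=prevalence * (1.0 - sensitivity),
        p_tn=(1.0 - prevalence) * specificity,
        p_fp=(1.0 - prevalence) * (1.0 - specificity),
    )


def _modality_accuracy(modality: str, params: ParameterSet) -> tuple[float, float]:
    if modality == "CE-CT":
        return params.sens_ct, params.spec_ct
    if modality == "PET/CT":
        return params.sens_pet, params.spec_pet
    raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


def strategy_outcome(
    modality: str,
    params: ParameterSet,
    conventions: Conventions = CALIBRATED_CONVENTIONS,
    life_table: Optional[LifeTable] = None,
    cost_convention: str = "embedded_index_ct",
    branch_outcomes: Optional[dict] = None,
) -> StrategyResult:
    """Expected cost and QALYs of one follow-up strategy.

    ``branch_outcomes`` may supply precomputed {BranchKind: BranchOutcome}
    (e.g. published values) to aggregate instead of running the engine.
    """
    if cost_convention not in COST_CONVENTIONS:
        raise ValueError(f"cost_convention must be one of {COST_CONVENTIONS}")
    sens, spec = _modality_accuracy(modality, params)
    weights = classify_test_outcomes(params.p_incomplete_ablation, sens, spec)
    if branch_outcomes is None:
        branch_outcomes = {
            kind: branch_outcome(kind, params, conventions, life_table)
            for kind in BranchKind
        }
    cost = sum(w * branch_outcomes[k].cost for k, w in weights.as_dict().items())
    qaly = sum(w * branch_outcomes[k].qaly for k, w in weights.as_dict().items())
    scan_cost = params.cost_ct if modality == "CE-CT" else params.cost_pet
    if cost_convention == "embedded_index_ct":
        # branch outcomes already carry one index CE-CT scan: add only the
        # PET/CT price differential (reproduces the published totals)
        cost += scan_cost - params.cost_ct
    else:
        # naive variant: bill the full modality price on top of the branches
        cost += scan_cost
    return StrategyResult(modality, float(cost), float(qaly))


def icer(reference: StrategyResult, comparator: StrategyResult) -> IcerResult:
    """ICER of ``comparator`` versus ``reference`` on unrounded outcomes."""
    d_cost = comparator.cost - reference.cost
    d_eff = comparator.qaly - reference.qaly
    if d_eff == 0.0 and d_cost == 0.0:
        return IcerResult(0.0, 0.0, None, "undefined")
    if d_eff == 0.0:
        return IcerResult(d_cost, 0.0, None, "dominated" if d_cost > 0 else "dominant")
    if d_eff > 0.0 and d_cost <= 0.0:
        return IcerResult(d_cost, d_eff, None, "dominant")
    if d_eff < 0.0 and d_cost >= 0.0:
        return IcerResult(d_cost, d_eff, None, "dominated")
    return IcerResult(d_cost, d_eff, d_cost / d_eff, "tradeoff")


def published_branch_outcomes() -> dict:
    """The published 2-year branch outcomes as :class:`BranchOutcome` objects.

    Survival was reported only for the FN and TN branches; the others carry
    NaN.  Useful for validating the decision-layer aggregation independently
    of the Markov engine's conventions.
    """
    from .markov import PRINTED_BRANCH_TARGETS

    return {
        t.kind: BranchOutcome(
            t.kind, t.cost, t.qaly, float("nan") if t.survival is None else t.survival
        )
        for t in PRINTED_BRANCH_TARGETS
    }
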