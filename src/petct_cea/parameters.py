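"""Model inputs: parameter container, life table, uncertainty distributions.

All quantities of the cost-effectiveness model live in a single validated
:class:`ParameterSet`: the one-time prevalence of incomplete ablation at the
follow-up scan, diagnostic sensitivities/specificities of contrast-enhanced CT
(CE-CT) and 18F-FDG PET/CT, per-event and per-year costs in 2019 USD,
health-state utilities, per-cycle/per-year transition probabilities, the
annual discount rate, the model horizon and the willingness-to-pay threshold.

Age-dependent background mortality comes from a :class:`LifeTable`
(``age, q_annual`` rows).  For probabilistic sensitivity analysis each
uncertain parameter carries a :class:`DistributionSpec` (beta for
probabilities/utilities, gamma for costs), parameterised by method of moments
from a mean and a standard error.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterSet",
    "LifeTable",
    "DistributionSpec",
    "ParameterValidationError",
    "load_parameters",
    "dump_parameters",
    "annual_to_cycle_prob",
    "background_mortality",
    "default_life_table",
    "default_distribution_specs",
]


class ParameterValidationError(ValueError):
    """A model input failed validation; the message names the field."""


_PROBABILITY_FIELDS = (
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
)

_COST_FIELDS = (
    "cost_ct",
    "cost_pet",
    "cost_ablation",
    "cost_hospital_day",
    "cost_reablation_total",
    "cost_cancer_yearly",
    "cost_no_cancer_yearly",
)


@dataclass(frozen=True)
class ParameterSet:
    """All model inputs of the follow-up imaging cost-effectiveness model.

    Defaults are the base-case values of the published model (2019 USD).
    Probabilities flagged ``_yr`` are annual and converted to per-cycle
    probabilities by the Markov engine; the others are applied on the basis
    chosen in the engine's :class:`~petct_cea.markov.Conventions`.
    """

    # prevalence of residual/locally progressing tumour at the follow-up scan
    p_incomplete_ablation: float = 0.30
    # diagnostic accuracy of the two imaging strategies
    sens_ct: float = 0.534
    spec_ct: float = 0.957
    sens_pet: float = 0.846
    spec_pet: float = 0.924
    # acute costs (USD)
    cost_ct: float = 385.00
    cost_pet: float = 1375.00
    cost_ablation: float = 1493.00
    hospital_days: int = 4
    cost_hospital_day: float = 2184.00
    cost_reablation_total: float = 10229.00
    delayed_reablation_multiplier: float = 1.3
    # long-term costs (USD per year)
    cost_cancer_yearly: float = 25000.00
    cost_no_cancer_yearly: float = 0.0
    # utilities
    u_first_month: float = 0.95
    u_no_recurrence: float = 1.0
    u_hepatic_recurrence: float = 0.65
    u_other_recurrence: float = 0.19
    u_death: float = 0.0
    # transition probabilities
    p_reablation_success: float = 0.93
    p_recurrence: float = 0.032
    p_mets_timely: float = 0.12
    p_mets_delayed: float = 0.15
    p_death_recurrence_yr: float = 0.0544
    p_remission_yr: float = 0.80
    # economics and horizon
    discount_rate_yr: float = 0.03
    horizon_months: int = 24
    cycle_months: int = 1
    start_age_years: float = 68.0
    wtp: float = 100_000.0

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterValidationError(
                    f"{name} must lie in [0, 1], got {v!r}"
                )
        for name in _COST_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ParameterValidationError(f"{name} must be >= 0, got {v!r}")
        if self.delayed_reablation_multiplier < 0:
            raise ParameterValidationError(
                "delayed_reablation_multiplier must be >= 0"
            )
        if not (0.0 <= self.discount_rate_yr <= 1.0):
            raise ParameterValidationError(
                f"discount_rate_yr must lie in [0, 1], got {self.discount_rate_yr!r}"
            )
        if self.cycle_months <= 0:
            raise ParameterValidationError("cycle_months must be positive")
        if self.horizon_months <= 0 or self.horizon_months % self.cycle_months:
            raise ParameterValidationError(
                "horizon_months must be a positive multiple of cycle_months"
            )
        if self.start_age_years < 0:
            raise ParameterValidationError("start_age_years must be >= 0")
        if self.wtp < 0:
            raise ParameterValidationError("wtp must be >= 0")
        if self.hospital_days < 0:
            raise ParameterValidationError("hospital_days must be >= 0")

    @property
    def cost_reablation_delayed(self) -> float:
        """Cost of a delayed reablation plus additional tests (USD)."""
        return self.delayed_reablation_multiplier * self.cost_reablation_total

    @property
    def n_cycles(self) -> int:
        return self.horizon_months // self.cycle_months

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def annual_to_cycle_prob(p_annual: float, cycle_months: float) -> float:
    """Convert an annual probability to a per-cycle probability.

    Assumes a constant hazard within the year:
    ``1 - (1 - p_annual) ** (cycle_months / 12)``.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ParameterValidationError(
            f"p_annual must lie in [0, 1], got {p_annual!r}"
        )
    if cycle_months <= 0:
        raise ParameterValidationError("cycle_months must be positive")
    return 1.0 - (1.0 - p_annual) ** (cycle_months / 12.0)


@dataclass(frozen=True)
class LifeTable:
    """Annual background death probabilities indexed by integer age.

    Lookup uses ``floor(age)``; ages below the first row clamp to the first
    row and ages beyond the last row clamp to the last row.
    """

    ages: np.ndarray
    q_annual: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        q = np.asarray(self.q_annual, dtype=float)
        if ages.size == 0:
            raise ParameterValidationError("life table must contain at least one row")
        if ages.size != q.size:
            raise ParameterValidationError("life table columns differ in length")
        if np.any(np.diff(ages) <= 0):
            raise ParameterValidationError("life table ages must strictly increase")
        if np.any((q < 0) | (q > 1)):
            raise ParameterValidationError("life table q_annual must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        """Read a ``age,q_annual`` CSV (header required)."""
        import pandas as pd

        frame = pd.read_csv(path)
        missing = {"age", "q_annual"} - set(frame.columns)
        if missing:
            raise ParameterValidationError(
                f"life table CSV lacks columns: {sorted(missing)}"
            )
        return cls(frame["age"].to_numpy(), frame["q_annual"].to_numpy())

    def annual_q(self, age_years: float) -> float:
        """Annual death probability at ``floor(age_years)``, clamped."""
        if age_years < 0:
            raise ParameterValidationError("age_years must be >= 0")
        idx = int(np.searchsorted(self.ages, math.floor(age_years), side="right")) - 1
        idx = min(max(idx, 0), self.ages.size - 1)
        return float(self.q_annual[idx])


def background_mortality(
    table: LifeTable, age_years: float, cycle_months: float
) -> float:
    """Per-cycle probability of death from background causes at ``age_years``."""
    return annual_to_cycle_prob(table.annual_q(age_years), cycle_months)


import functools


@functools.lru_cache(maxsize=1)
def default_life_table() -> LifeTable:
    """Packaged synthetic stand-in for the US 2015 all-population life table.

    Gompertz approximation of all-cause annual death probability by age,
    calibrated to the overall level and slope of published US mortality
    around the model's age range; packaged as a plain CSV.
    """
    ref = resources.files("petct_cea.data").joinpath(
        "synthetic_us2015_life_table.csv"
    )
    with resources.as_file(ref) as path:
        return LifeTable.from_csv(path)


# ---------------------------------------------------------------------------
# Parameter (de)serialisation


def _defaults_dict() -> dict:
    ref = resources.files("petct_cea.data").joinpath("table1_defaults.json")
    return json.loads(ref.read_text())


def load_parameters(source=None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a config source.

    Parameters
    ----------
    source
        ``None`` (packaged base-case defaults), a mapping of field names to
        values, or a path to a JSON/YAML document whose keys are ParameterSet
        field names.  Missing fields fall back to the base-case defaults;
        unknown fields raise rather than being silently ignored.
    """
    if source is None:
        overrides: Mapping = {}
    elif isinstance(source, Mapping):
        overrides = dict(source)
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            overrides = yaml.safe_load(text) or {}
        else:
            overrides = json.loads(text) if text.strip() else {}
        if not isinstance(overrides, Mapping):
            raise ParameterValidationError(
                f"parameter file {path} must contain a mapping"
            )

    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(overrides) - known
    if unknown:
        raise ParameterValidationError(
            f"unknown parameter field(s): {sorted(unknown)}"
        )
    values = _defaults_dict()
    values.update(overrides)
    return ParameterSet(**values)


def dump_parameters(params: ParameterSet, path) -> None:
    """Serialise a ParameterSet to JSON or YAML (by file extension)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Uncertainty distributions for probabilistic sensitivity analysis


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one uncertain parameter.

    ``beta`` for quantities bounded in [0, 1], ``gamma`` for non-negative
    quantities, ``fixed`` for parameters held at their mean.  ``dispersion``
    is the standard error expressed as a fraction of the mean; shape
    parameters follow by method of moments.
    """

    name: str
    family: str  # "beta" | "gamma" | "fixed"
    mean: float
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in {"beta", "gamma", "fixed"}:
            raise ParameterValidationError(
                f"{self.name}: unknown distribution family {self.family!r}"
            )
        if self.family == "beta" and not (0.0 <= self.mean <= 1.0):
            raise ParameterValidationError(
                f"{self.name}: beta mean must lie in [0, 1]"
            )
        if self.family == "gamma" and self.mean < 0:
            raise ParameterValidationError(
                f"{self.name}: gamma mean must be >= 0"
            )
        if self.dispersion < 0:
            raise ParameterValidationError(
                f"{self.name}: dispersion must be >= 0"
            )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` values; degenerate specs return the mean."""
        m = self.mean
        se = self.dispersion * m
        if self.family == "fixed" or se == 0.0 or m == 0.0:
            return np.full(size, m)
        if self.family == "beta":
            var_cap = m * (1.0 - m)
            if se**2 >= var_cap:
                # method of moments needs var < m(1-m); shrink to stay proper
                warnings.warn(
                    f"{self.name}: beta dispersion implies variance >= m(1-m); "
                    "shrinking standard error",
                    stacklevel=2,
                )
                se = 0.95 * math.sqrt(var_cap)
            nu = m * (1.0 - m) / se**2 - 1.0
            return rng.beta(m * nu, (1.0 - m) * nu, size=size)
        shape = (m / se) ** 2
        scale = se**2 / m
        return rng.gamma(shape, scale, size=size)


# parameters marked beta/gamma in the base-case input table; utilities pinned
# at the scale ends (1.0, 0.0) and zero costs are held fixed
_BETA_PARAMS = (
    "p_incomplete_ablation",
    "sens_ct",
    "spec_ct",
    "sens_pet",
    "spec_pet",
    "u_first_month",
    "u_hepatic_recurrence",
    "u_other_recurrence",
    "p_reablation_success",
    "p_recurrence",
    "p_mets_timely",
    "p_mets_delayed",
    "p_death_recurrence_yr",
    "p_remission_yr",
)
_GAMMA_PARAMS = (
    "cost_ct",
    "cost_pet",
    "cost_ablation",
    "cost_hospital_day",
    "cost_reablation_total",
    "cost_cancer_yearly",
)


def default_distribution_specs(
    params: ParameterSet,
    prob_se_frac: float = 0.10,
    cost_se_frac: float = 0.20,
) -> tuple[DistributionSpec, ...]:
    """Default PSA distributions: beta (SE = 10% of mean) for probabilities
    and utilities, gamma (SE = 20% of mean) for costs; boundary values fixed.
    """
    specs: list[DistributionSpec] = []
    for name in _BETA_PARAMS:
        mean = getattr(params, name)
        frac = prob_se_frac if 0.0 < mean < 1.0 else 0.0
        specs.append(DistributionSpec(name, "beta", mean, frac))
    for name in _GAMMA_PARAMS:
        mean = getattr(params, name)
        frac = cost_se_frac if mean > 0 else 0.0
        specs.append(DistributionSpec(name, "gamma", mean, frac))
    return tuple(specs)
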