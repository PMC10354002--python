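"""Incremental monthly cost of a scenario from category cost lines.

Costing follows a health-system perspective: only the additional costs of
modifying the service are counted, and they are allocated to the additional
adolescent patients the modification attracts.  Each cost line carries a
monthly amount in 2019 South African Rand (ZAR) and an allocation rule:

``none_incremental``
    contributes nothing (e.g. assets — no new assets are needed);
``per_visit``
    a per-visit unit cost times the additional adolescents (supplies);
``shared_all_patients``
    the monthly amount shared over all patients, with the additional
    adolescents' share charged: ``amount * add / (headcount + add)``
    (utilities and other overheads);
``extra_room_overhead``
    a counselling-room share of overheads, charged only when the scenario
    needs extra space (youth-only or afternoon services);
``afternoon_staff_time``
    a fraction of monthly staff expenditure covering the afternoon
    extension, charged only for afternoon scenarios;
``all_adolescents_billed_to_additional``
    a per-adolescent unit amount times ALL adolescents (baseline +
    additional), billed to the additional ones (subsidized food);
``fixed_monthly``
    the whole monthly amount whenever the gating attribute is in the
    scenario (Wi-Fi supply for the facility).

Amounts convert to USD at a configurable mid-year exchange rate
(default 1 USD = 14 ZAR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .choice_model import InputError, Scenario
from .uptake import ClinicProfile, UptakeProjection

__all__ = [
    "ALLOCATION_KINDS",
    "ConfigurationError",
    "CostConfig",
    "CostLine",
    "ScenarioCost",
    "allocate",
    "scenario_cost",
    "convert_currency",
]

ALLOCATION_KINDS = (
    "none_incremental",
    "per_visit",
    "shared_all_patients",
    "extra_room_overhead",
    "afternoon_staff_time",
    "all_adolescents_billed_to_additional",
    "fixed_monthly",
)

#: default scenario gates per allocation kind: the rule contributes only
#: when the scenario switches at least one of these attributes (None = no
#: gate).  Overridable per line via a ``gate`` param ("attr" or "a|b").
_DEFAULT_GATES: dict[str, tuple[str, ...] | None] = {
    "none_incremental": None,
    "per_visit": None,
    "shared_all_patients": None,
    "extra_room_overhead": ("youth_only", "afternoon"),
    "afternoon_staff_time": ("afternoon",),
    "all_adolescents_billed_to_additional": ("food",),
    "fixed_monthly": (),  # fixed costs must name their gate explicitly
}


class ConfigurationError(ValueError):
    """Raised for invalid cost/config inputs (unknown rule, missing param)."""


@dataclass(frozen=True)
class CostConfig:
    """Knobs the costing model leaves to the analyst.

    exchange_rate
        ZAR per USD (default 14, the 2019 mid-year rate).
    afternoon_hours_fraction
        Fraction of monthly staff expenditure attributable to the afternoon
        extension (marginal roster over extra open hours).
    room_share
        One average counselling room's share of facility overheads.
    """

    exchange_rate: float = 14.0
    afternoon_hours_fraction: float = 0.016
    room_share: float = 0.015

    def __post_init__(self) -> None:
        if self.exchange_rate <= 0:
            raise ConfigurationError(
                f"exchange_rate must be > 0, got {self.exchange_rate!r}"
            )
        for name in ("afternoon_hours_fraction", "room_share"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class CostLine:
    """One cost category with its monthly amount and allocation rule."""

    category: str
    monthly_amount_zar: float
    kind: str
    params: Mapping[str, str | float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.monthly_amount_zar < 0:
            raise ConfigurationError(
                f"monthly_amount_zar must be >= 0 for {self.category!r}"
            )
        if self.kind not in ALLOCATION_KINDS:
            raise ConfigurationError(
                f"unknown allocation kind {self.kind!r} for {self.category!r}; "
                f"known kinds: {', '.join(ALLOCATION_KINDS)}"
            )

    def param(self, name: str) -> float:
        try:
            return float(self.params[name])
        except KeyError:
            raise ConfigurationError(
                f"cost line {self.category!r} ({self.kind}) is missing "
                f"required param {name!r}"
            ) from None

    def gate(self) -> tuple[str, ...] | None:
        if "gate" in self.params:
            return tuple(str(self.params["gate"]).split("|"))
        default = _DEFAULT_GATES[self.kind]
        if default == ():
            raise ConfigurationError(
                f"cost line {self.category!r} ({self.kind}) is missing "
                "required param 'gate'"
            )
        return default


@dataclass(frozen=True)
class ScenarioCost:
    """Incremental monthly cost of one scenario, in USD.

    ``cost_per_additional`` is NaN (undefined) when the scenario attracts no
    additional adolescents but still incurs cost.
    """

    scenario: Scenario
    by_category: Mapping[str, float]
    total_monthly: float
    cost_per_additional: float


def convert_currency(amount_zar: float, rate: float = 14.0) -> float:
    """Convert ZAR to USD at ``rate`` ZAR per USD."""
    if rate <= 0:
        raise ConfigurationError(f"exchange rate must be > 0, got {rate!r}")
    if not math.isfinite(amount_zar):
        raise InputError(f"amount must be finite, got {amount_zar!r}")
    return amount_zar / rate


def allocate(
    line: CostLine,
    scenario: Scenario,
    projection: UptakeProjection,
    profile: ClinicProfile,
    config: CostConfig | None = None,
) -> float:
    """Monthly USD allocated to the additional adolescents by one line."""
    config = config or CostConfig()
    gate = line.gate()
    if gate is not None and not any(scenario.has_attribute(a) for a in gate):
        return 0.0

    add = projection.additional_per_month
    if line.kind == "none_incremental":
        zar = 0.0
    elif line.kind == "per_visit":
        if "unit_cost_zar" in line.params:
            unit = line.param("unit_cost_zar")
        else:
            unit = line.monthly_amount_zar / profile.total_monthly_headcount
        zar = unit * add
    elif line.kind == "shared_all_patients":
        zar = line.monthly_amount_zar * add / (profile.total_monthly_headcount + add)
    elif line.kind == "extra_room_overhead":
        share = (
            line.param("room_share") if "room_share" in line.params else config.room_share
        )
        zar = share * line.monthly_amount_zar
    elif line.kind == "afternoon_staff_time":
        fraction = (
            line.param("afternoon_hours_fraction")
            if "afternoon_hours_fraction" in line.params
            else config.afternoon_hours_fraction
        )
        zar = fraction * line.monthly_amount_zar
    elif line.kind == "all_adolescents_billed_to_additional":
        unit = line.param("unit_cost_zar")
        zar = unit * (profile.baseline_adolescents_per_month + add)
    elif line.kind == "fixed_monthly":
        zar = line.monthly_amount_zar
    else:  # pragma: no cover - rejected in CostLine.__post_init__
        raise ConfigurationError(f"unknown allocation kind {line.kind!r}")
    return convert_currency(zar, rate=config.exchange_rate)


def scenario_cost(
    scenario: Scenario,
    lines: Sequence[CostLine],
    projection: UptakeProjection,
    profile: ClinicProfile,
    config: CostConfig | None = None,
) -> ScenarioCost:
    """Sum allocations over all cost lines for one scenario.

    The cost per additional adolescent uses the unrounded additional count;
    all arithmetic is at full precision (round only for display).
    """
    if not lines:
        raise InputError("at least one cost line is required")
    config = config or CostConfig()
    by_category: dict[str, float] = {}
    for line in lines:
        usd = allocate(line, scenario, projection, profile, config)
        by_category[line.category] = by_category.get(line.category, 0.0) + usd
    total = sum(by_category.values())
    if projection.additional_unrounded > 0:
        per_additional = total / projection.additional_unrounded
    elif total == 0.0:
        per_additional = 0.0
    else:
        per_additional = math.nan
    return ScenarioCost(
        scenario=scenario,
        by_category=by_category,
        total_monthly=total,
        cost_per_additional=per_additional,
    )
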