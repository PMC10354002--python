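"""Re-run the uptake -> cost -> frontier pipeline at a CI bound.

Stated-preference experiments can over-state real-world uptake, so the
whole analysis is repeated with every scenario's uptake delta replaced by
the lower (or upper) bound of its 95% confidence interval.  Negative
projections are clamped at a configurable floor (0 by default; 1 matches
published sensitivity tables that never report fewer than one additional
adolescent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import math

import pandas as pd

from .cea import FrontierResult, Strategy, build_frontier
from .choice_model import InputError, Scenario, UptakeDelta
from .costing import CostConfig, CostLine, ScenarioCost, scenario_cost
from .uptake import ClinicProfile, UptakeProjection, project

__all__ = ["SensitivitySpec", "ScenarioEvaluation", "evaluate_scenarios", "run_sensitivity"]

_BOUNDS = ("point", "lower", "upper")


@dataclass(frozen=True)
class SensitivitySpec:
    """Which CI bound to evaluate, and the clamp floor for negative deltas."""

    bound: str = "lower"
    clamp_floor: int = 0

    def __post_init__(self) -> None:
        if self.bound not in _BOUNDS:
            raise InputError(f"bound must be one of {_BOUNDS}, got {self.bound!r}")
        if self.clamp_floor < 0:
            raise InputError("clamp_floor must be >= 0")


@dataclass(frozen=True)
class ScenarioEvaluation:
    """Joint uptake / cost / frontier view of a set of scenarios."""

    projections: tuple[UptakeProjection, ...]
    costs: tuple[ScenarioCost, ...]
    frontier: FrontierResult

    def table(self) -> pd.DataFrame:
        """Table mirroring the published per-clinic layout."""
        labels = self.frontier.labels
        icers = self.frontier.icers
        rows = []
        for proj, cost in zip(self.projections, self.costs):
            name = proj.scenario.name
            rows.append(
                {
                    "strategy": name,
                    "additional_per_month": proj.additional_per_month,
                    "total_per_month": proj.total_per_month,
                    "delta_pp": proj.delta_pp,
                    "cost_per_additional_usd": cost.cost_per_additional,
                    "total_cost_usd": cost.total_monthly,
                    "status": labels[name],
                    "icer_usd": icers.get(name, math.nan),
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values("total_cost_usd", kind="mergesort").reset_index(drop=True)


def evaluate_scenarios(
    scenarios: Sequence[Scenario],
    deltas_pp: Sequence[float],
    profile: ClinicProfile,
    lines: Sequence[CostLine],
    config: CostConfig | None = None,
    floor: int = 0,
    use_unrounded: bool = False,
) -> ScenarioEvaluation:
    """Project uptake, cost every scenario, and build the frontier."""
    config = config or CostConfig()
    projections = project(profile, scenarios, deltas_pp, floor=floor)
    costs = [
        scenario_cost(s, lines, p, profile, config)
        for s, p in zip(scenarios, projections)
    ]
    strategies = [
        Strategy(
            name=s.name,
            effect=p.additional_per_month,
            cost=c.total_monthly,
            effect_unrounded=p.additional_unrounded,
        )
        for s, p, c in zip(scenarios, projections, costs)
    ]
    frontier = build_frontier(strategies, use_unrounded=use_unrounded)
    return ScenarioEvaluation(
        projections=tuple(projections), costs=tuple(costs), frontier=frontier
    )


def run_sensitivity(
    spec: SensitivitySpec,
    scenarios: Sequence[Scenario],
    deltas: Sequence[UptakeDelta],
    profile: ClinicProfile,
    lines: Sequence[CostLine],
    config: CostConfig | None = None,
    use_unrounded: bool = False,
) -> ScenarioEvaluation:
    """Substitute the chosen CI bound for every delta and re-run the pipeline.

    With ``bound='point'`` this reproduces the base case exactly.
    """
    if len(scenarios) != len(deltas):
        raise InputError(f"{len(scenarios)} scenario(s) but {len(deltas)} delta(s)")
    bounded: list[float] = []
    for scenario, delta in zip(scenarios, deltas):
        if not isinstance(delta, UptakeDelta):
            raise InputError(
                f"scenario {scenario.name!r} needs an UptakeDelta with CI bounds"
            )
        bounded.append(delta.at_bound(spec.bound))
    return evaluate_scenarios(
        scenarios,
        bounded,
        profile,
        lines,
        config=config,
        floor=spec.clamp_floor,
        use_unrounded=use_unrounded,
    )
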