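"""Convert uptake deltas into counts of additional adolescents per clinic.

A clinic is summarized by its baseline number of adolescent clients per
month and the share of all clinic users they represent.  An uptake delta of
``delta_pp`` percentage points translates into
``additional = round(N_base * delta_pp / 100)`` additional adolescents per
month (half-away-from-zero rounding, which reproduces every internally
consistent published count), clamped below at a configurable floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .choice_model import InputError, Scenario, UptakeDelta

__all__ = [
    "ClinicProfile",
    "AdditionalCount",
    "UptakeProjection",
    "additional_adolescents",
    "project",
    "annualize",
]


@dataclass(frozen=True)
class ClinicProfile:
    """Monthly client volumes of one primary health clinic."""

    clinic_name: str
    baseline_adolescents_per_month: int
    baseline_uptake_share_pct: float
    total_monthly_headcount: int

    def __post_init__(self) -> None:
        if self.baseline_adolescents_per_month < 0:
            raise InputError("baseline_adolescents_per_month must be >= 0")
        if not (0.0 < self.baseline_uptake_share_pct < 100.0):
            raise InputError(
                "baseline_uptake_share_pct must be in (0, 100), got "
                f"{self.baseline_uptake_share_pct!r}"
            )

    @property
    def baseline_prob(self) -> float:
        return self.baseline_uptake_share_pct / 100.0


class AdditionalCount(NamedTuple):
    count: int
    unrounded: float


def _round_half_away_from_zero(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def additional_adolescents(
    profile: ClinicProfile, delta_pp: float, floor: int = 0
) -> AdditionalCount:
    """Additional adolescents per month implied by an uptake delta.

    Returns both the integer count (half-away-from-zero rounding, clamped
    below at ``floor``) and the unrounded value used for cost-per-patient
    arithmetic.  ``floor=1`` reproduces published sensitivity tables that
    report 1 additional adolescent for negative deltas.
    """
    if not math.isfinite(delta_pp):
        raise InputError(f"delta_pp must be finite, got {delta_pp!r}")
    unrounded = profile.baseline_adolescents_per_month * delta_pp / 100.0
    count = max(_round_half_away_from_zero(unrounded), floor)
    return AdditionalCount(count=count, unrounded=max(unrounded, float(floor)))


@dataclass(frozen=True)
class UptakeProjection:
    """Projected monthly adolescent volumes for one scenario at one clinic."""

    scenario: Scenario
    delta_pp: float
    additional_per_month: int
    additional_unrounded: float
    total_per_month: int

    def __post_init__(self) -> None:
        expected = self.total_per_month - self.additional_per_month
        if self.additional_per_month < 0:
            raise InputError("additional_per_month must be >= 0 after clamping")
        if expected < 0:
            raise InputError("total_per_month must be >= additional_per_month")


def project(
    profile: ClinicProfile,
    scenarios: Sequence[Scenario],
    deltas: Sequence[UptakeDelta | float],
    floor: int = 0,
) -> list[UptakeProjection]:
    """One :class:`UptakeProjection` per scenario.

    ``deltas`` may hold :class:`UptakeDelta` objects (their point estimate
    is used) or plain percentage-point floats.
    """
    if len(scenarios) != len(deltas):
        raise InputError(f"{len(scenarios)} scenario(s) but {len(deltas)} delta(s)")
    out: list[UptakeProjection] = []
    for scenario, delta in zip(scenarios, deltas):
        delta_pp = delta.delta_pp if isinstance(delta, UptakeDelta) else float(delta)
        add = additional_adolescents(profile, delta_pp, floor=floor)
        out.append(
            UptakeProjection(
                scenario=scenario,
                delta_pp=delta_pp,
                additional_per_month=add.count,
                additional_unrounded=add.unrounded,
                total_per_month=profile.baseline_adolescents_per_month + add.count,
            )
        )
    return out


def annualize(projection: UptakeProjection) -> int:
    """Additional adolescents over a 1-year horizon (12 x monthly count)."""
    return 12 * projection.additional_per_month
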