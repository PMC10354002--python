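"""Conditional-logit choice model for service-attribute bundles.

A discrete choice experiment (DCE) estimates, for each attribute level of a
hypothetical service (free Wi-Fi, subsidized food, afternoon hours,
youth-only waiting areas, ...), a conditional-logit utility coefficient
``beta`` relative to a reference ("baseline") service configuration. This
module holds those coefficients, evaluates the linear utility index
``beta' x`` of any bundle of switched-on levels, converts utilities into
choice probabilities via the softmax

    P_i = exp(beta' x_i) / sum_j exp(beta' x_j),

and translates a bundle into an incremental uptake probability: the change,
in percentage points, of the probability that an adolescent chooses to use
the service when the bundle is offered instead of the baseline service.

The uptake translation is a two-alternative contrast (modified service vs
status quo): the status-quo utility is anchored so that its choice
probability equals the observed baseline uptake share, and the modified
service shifts the log-odds by the bundle's summed coefficients.  Standard
errors propagate by the delta method on the probability scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "Z95",
    "InputError",
    "AttributeLevel",
    "CoefficientSet",
    "Scenario",
    "UptakeDelta",
    "utility",
    "utility_std_error",
    "choice_probability",
    "delta_uptake",
    "enumerate_scenarios",
    "tabulate_uptake",
]

#: two-sided 95% normal quantile used for all confidence intervals
Z95 = 1.959964


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


@dataclass(frozen=True)
class AttributeLevel:
    """One non-reference level of a service attribute.

    Parameters
    ----------
    attribute
        Attribute name, e.g. ``"wifi"`` or ``"staff_attitude"``.
    level
        Level name within the attribute, e.g. ``"Wi-Fi"`` or ``"Friendly"``.
    coefficient
        Conditional-logit utility shift relative to the attribute's
        reference level (dimensionless, log-odds units).
    std_error
        Standard error of ``coefficient`` (same units); must be >= 0.
    modifiable
        Whether the level belongs to the readily implementable
        ("modifiable") set, as opposed to nuanced attributes such as staff
        friendliness that cannot be costed in a generalizable way.
    """

    attribute: str
    level: str
    coefficient: float
    std_error: float = 0.0
    modifiable: bool = True

    def __post_init__(self) -> None:
        if self.std_error < 0:
            raise InputError(
                f"std_error must be >= 0, got {self.std_error!r} for "
                f"({self.attribute}, {self.level})"
            )


class CoefficientSet:
    """An ordered collection of :class:`AttributeLevel` plus the baseline.

    ``baseline`` maps each attribute name to the name of its reference
    level (the configuration reflecting current practice).  Reference
    levels carry coefficient 0 by reference coding and need not appear in
    ``levels``; attributes missing from ``baseline`` get an implicit
    reference level named ``"<reference>"``.
    """

    def __init__(
        self,
        levels: Iterable[AttributeLevel],
        baseline: Mapping[str, str] | None = None,
    ) -> None:
        self.levels: tuple[AttributeLevel, ...] = tuple(levels)
        seen: set[tuple[str, str]] = set()
        for lv in self.levels:
            key = (lv.attribute, lv.level)
            if key in seen:
                raise InputError(f"duplicate attribute/level pair {key!r}")
            seen.add(key)
        base = dict(baseline or {})
        for lv in self.levels:
            base.setdefault(lv.attribute, "<reference>")
        for attr, ref in base.items():
            if (attr, ref) in seen:
                ref_level = self[attr, ref]
                if ref_level.coefficient != 0.0:
                    raise InputError(
                        f"baseline level ({attr}, {ref}) must have "
                        f"coefficient 0, got {ref_level.coefficient}"
                    )
        self.baseline: dict[str, str] = base

    def __iter__(self) -> Iterator[AttributeLevel]:
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, key: tuple[str, str]) -> AttributeLevel:
        attribute, level = key
        for lv in self.levels:
            if lv.attribute == attribute and lv.level == level:
                return lv
        raise InputError(f"unknown attribute/level pair ({attribute!r}, {level!r})")

    @property
    def attributes(self) -> tuple[str, ...]:
        out: list[str] = []
        for lv in self.levels:
            if lv.attribute not in out:
                out.append(lv.attribute)
        return tuple(out)

    def select(self, only_modifiable: bool = True) -> tuple[AttributeLevel, ...]:
        if only_modifiable:
            return tuple(lv for lv in self.levels if lv.modifiable)
        return self.levels


@dataclass(frozen=True)
class Scenario:
    """A bundle of attribute levels switched on relative to the baseline.

    ``switched`` holds (attribute, level) pairs; at most one level per
    attribute.  The empty bundle is the valid baseline scenario.
    """

    name: str
    switched: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        attrs = [a for a, _ in self.switched]
        if len(attrs) != len(set(attrs)):
            raise InputError(
                f"scenario {self.name!r} switches more than one level of "
                f"the same attribute: {self.switched!r}"
            )

    @classmethod
    def baseline(cls) -> "Scenario":
        return cls(name="baseline", switched=())

    def has_attribute(self, attribute: str) -> bool:
        return any(a == attribute for a, _ in self.switched)

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.switched)


@dataclass(frozen=True)
class UptakeDelta:
    """Percentage-point change in uptake probability with a symmetric CI."""

    delta_pp: float
    se_pp: float
    ci_low_pp: float
    ci_high_pp: float

    def __post_init__(self) -> None:
        if not (self.ci_low_pp <= self.delta_pp <= self.ci_high_pp):
            raise InputError(
                f"CI [{self.ci_low_pp}, {self.ci_high_pp}] does not bracket "
                f"delta_pp={self.delta_pp}"
            )

    @classmethod
    def from_point(cls, delta_pp: float, se_pp: float, z: float = Z95) -> "UptakeDelta":
        return cls(
            delta_pp=delta_pp,
            se_pp=se_pp,
            ci_low_pp=delta_pp - z * se_pp,
            ci_high_pp=delta_pp + z * se_pp,
        )

    def at_bound(self, bound: str) -> float:
        """Return the delta at ``bound`` in {'point', 'lower', 'upper'}."""
        if bound == "point":
            return self.delta_pp
        if bound == "lower":
            return self.ci_low_pp
        if bound == "upper":
            return self.ci_high_pp
        raise InputError(f"unknown bound {bound!r}")


def utility(scenario: Scenario, coeffs: CoefficientSet) -> float:
    """Linear utility index ``beta' x`` of a scenario.

    Baseline levels contribute 0 by reference coding, so the result is the
    sum of the switched levels' coefficients.
    """
    return float(sum(coeffs[pair].coefficient for pair in scenario.switched))


def utility_std_error(
    scenario: Scenario,
    coeffs: CoefficientSet,
    covariance: pd.DataFrame | np.ndarray | None = None,
) -> float:
    """Standard error of the scenario's summed utility.

    Without a coefficient covariance matrix the level estimates are treated
    as independent (``sqrt(sum se_i^2)``); with one, the full quadratic form
    ``sqrt(x' Sigma x)`` is used.  ``covariance`` may be a DataFrame indexed
    and columned by ``"attribute:level"`` keys, or an array ordered like
    ``coeffs.levels``.
    """
    if not scenario.switched:
        return 0.0
    if covariance is None:
        return float(
            np.sqrt(sum(coeffs[pair].std_error ** 2 for pair in scenario.switched))
        )
    keys = [f"{lv.attribute}:{lv.level}" for lv in coeffs.levels]
    if isinstance(covariance, pd.DataFrame):
        sigma = covariance.loc[keys, keys].to_numpy(dtype=float)
    else:
        sigma = np.asarray(covariance, dtype=float)
        if sigma.shape != (len(keys), len(keys)):
            raise InputError(
                f"covariance shape {sigma.shape} does not match the "
                f"{len(keys)} coefficient(s)"
            )
    x = np.array(
        [1.0 if (lv.attribute, lv.level) in set(scenario.switched) else 0.0 for lv in coeffs.levels]
    )
    return float(np.sqrt(x @ sigma @ x))


def choice_probability(utilities: Sequence[float]) -> np.ndarray:
    """Softmax choice probabilities over the alternatives in one task.

    Shift-invariant in the utilities; components lie in (0, 1) and sum to 1.
    """
    u = np.asarray(utilities, dtype=float)
    if u.ndim != 1 or u.size < 2:
        raise InputError("choice_probability needs at least 2 alternatives")
    if not np.all(np.isfinite(u)):
        raise InputError("utilities must be finite")
    e = np.exp(u - u.max())
    return e / e.sum()


def delta_uptake(
    scenario: Scenario,
    coeffs: CoefficientSet,
    baseline_prob: float,
    z: float = Z95,
    covariance: pd.DataFrame | np.ndarray | None = None,
) -> UptakeDelta:
    """Incremental uptake probability of a scenario, in percentage points.

    The two-alternative contrast shifts the baseline log-odds by the
    scenario's utility:

        delta_pp = 100 * [ expit(logit(p0) + beta'x) - p0 ].

    The standard error follows by the delta method on the probability scale,
    ``se_pp = 100 * p * (1 - p) * se(beta'x)`` evaluated at the shifted
    probability ``p``; the 95% CI is symmetric on the percentage-point
    scale.
    """
    if not (0.0 < baseline_prob < 1.0):
        raise InputError(f"baseline_prob must be in (0, 1), got {baseline_prob!r}")
    u = utility(scenario, coeffs)
    se_u = utility_std_error(scenario, coeffs, covariance)
    # expit(logit(p)) round-trips with ~1 ulp error; keep beta=0 exact
    p = baseline_prob if u == 0.0 else float(expit(logit(baseline_prob) + u))
    delta_pp = 100.0 * (p - baseline_prob)
    se_pp = 100.0 * p * (1.0 - p) * se_u
    return UptakeDelta.from_point(delta_pp, se_pp, z=z)


def enumerate_scenarios(
    coeffs: CoefficientSet, only_modifiable: bool = True
) -> list[Scenario]:
    """All non-empty attribute-level bundles, one level per attribute.

    For k attributes with a single non-reference level each this yields
    ``2^k - 1`` mutually exclusive combinations (15 for the four modifiable
    attributes).  Deterministic order: by bundle size, then lexicographic
    by name.
    """
    selected = coeffs.select(only_modifiable=only_modifiable)
    if not selected:
        raise InputError("no attribute levels match the requested filter")
    by_attr: dict[str, list[AttributeLevel]] = {}
    for lv in selected:
        by_attr.setdefault(lv.attribute, []).append(lv)
    scenarios: list[Scenario] = []
    options = [[None, *lvs] for lvs in by_attr.values()]
    for combo in itertools.product(*options):
        chosen = [lv for lv in combo if lv is not None]
        if not chosen:
            continue
        name = " + ".join(lv.level for lv in chosen)
        scenarios.append(
            Scenario(name=name, switched=tuple((lv.attribute, lv.level) for lv in chosen))
        )
    scenarios.sort(key=lambda s: (len(s.switched), s.name))
    return scenarios


def tabulate_uptake(
    scenarios: Sequence[Scenario],
    deltas: Sequence[UptakeDelta],
    baseline_share: float,
) -> pd.DataFrame:
    """Per-scenario uptake shares: ``total = baseline_share + delta_pp``.

    ``baseline_share`` and the output are percentages of all clinic users;
    the total column is reported to 2 decimals as in published uptake
    tables.
    """
    if not (0.0 < baseline_share < 100.0):
        raise InputError(f"baseline_share must be in (0, 100), got {baseline_share!r}")
    if len(scenarios) != len(deltas):
        raise InputError(
            f"{len(scenarios)} scenario(s) but {len(deltas)} delta(s)"
        )
    rows = [
        {
            "scenario": s.name,
            "delta_pp": d.delta_pp,
            "ci_low_pp": d.ci_low_pp,
            "ci_high_pp": d.ci_high_pp,
            "total_share_pct": round(baseline_share + d.delta_pp, 2),
        }
        for s, d in zip(scenarios, deltas)
    ]
    return pd.DataFrame(rows)
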