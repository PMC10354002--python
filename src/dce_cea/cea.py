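"""Incremental cost-effectiveness analysis over a strategy set.

Each strategy is a point (effect, cost): additional adolescents using
services per month, and total incremental USD per month.  The engine

1. removes *strictly dominated* strategies — some competitor (or the
   implicit zero-cost, zero-effect "do nothing" baseline) is at least as
   effective and no more costly, with one comparison strict;
2. removes *weakly (extended) dominated* strategies — any strategy whose
   ICER against the next-cheaper survivor exceeds the ICER of the next-
   more-effective survivor against it, iterating with ICERs recomputed
   after each removal.  The survivors are exactly the vertices of the
   lower-left convex hull of the (effect, cost) cloud including the origin;
3. orders the survivors by increasing cost and attaches each one's ICER
   against its predecessor on the frontier (the first against the
   baseline), yielding a ladder of strictly increasing ICERs — the
   efficient menu for an increasing budget.

No willingness-to-pay threshold is applied; the output is the frontier
itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .choice_model import InputError

__all__ = [
    "NON_DOMINATED",
    "DOMINATED",
    "WEAKLY_DOMINATED",
    "Strategy",
    "FrontierEntry",
    "FrontierResult",
    "UndefinedComparisonError",
    "pairwise_icer",
    "eliminate_dominated",
    "eliminate_extended_dominance",
    "build_frontier",
]

NON_DOMINATED = "non_dominated"
DOMINATED = "dominated"
WEAKLY_DOMINATED = "weakly_dominated"


class UndefinedComparisonError(ValueError):
    """Raised when an ICER is requested for strategies of equal effect."""


@dataclass(frozen=True)
class Strategy:
    """One intervention bundle's monthly effect and cost.

    ``effect`` is the integer additional-adolescent count matching printed
    tables; ``effect_unrounded`` optionally carries the full-precision
    companion used when the engine runs with ``use_unrounded=True``.
    """

    name: str
    effect: float
    cost: float
    effect_unrounded: float | None = None

    def __post_init__(self) -> None:
        if self.effect < 0 or self.cost < 0:
            raise InputError(
                f"strategy {self.name!r} must have effect >= 0 and cost >= 0"
            )

    def effect_value(self, use_unrounded: bool = False) -> float:
        if use_unrounded and self.effect_unrounded is not None:
            return self.effect_unrounded
        return self.effect


@dataclass(frozen=True)
class FrontierEntry:
    strategy: Strategy
    label: str
    icer: float | None  # vs the previous frontier strategy; None unless non-dominated


@dataclass(frozen=True)
class FrontierResult:
    """Per-strategy labels and the ICER ladder, ordered by increasing cost."""

    entries: tuple[FrontierEntry, ...]

    @property
    def frontier(self) -> tuple[FrontierEntry, ...]:
        return tuple(e for e in self.entries if e.label == NON_DOMINATED)

    @property
    def labels(self) -> dict[str, str]:
        return {e.strategy.name: e.label for e in self.entries}

    @property
    def icers(self) -> dict[str, float]:
        return {e.strategy.name: e.icer for e in self.frontier}


def pairwise_icer(a: Strategy, b: Strategy, use_unrounded: bool = False) -> float:
    """Incremental cost per additional adolescent of ``a`` versus ``b``."""
    ea, eb = a.effect_value(use_unrounded), b.effect_value(use_unrounded)
    if ea == eb:
        raise UndefinedComparisonError(
            f"strategies {a.name!r} and {b.name!r} have equal effect {ea}; "
            "resolve the pair by dominance, not an ICER"
        )
    return (a.cost - b.cost) / (ea - eb)


_ORIGIN = Strategy(name="__baseline__", effect=0.0, cost=0.0, effect_unrounded=0.0)


def _points(
    strategies: Sequence[Strategy], use_unrounded: bool
) -> list[tuple[str, float, float]]:
    return [(s.name, s.effect_value(use_unrounded), s.cost) for s in strategies]


def eliminate_dominated(
    strategies: Sequence[Strategy], use_unrounded: bool = False
) -> dict[str, bool]:
    """Map strategy name -> strictly dominated?

    A strategy is strictly dominated iff some other strategy (or the
    zero-cost, zero-effect baseline) has cost <= its cost and effect >= its
    effect with at least one comparison strict.  Input order never affects
    the result.
    """
    if not strategies:
        raise InputError("at least one strategy is required")
    names = [s.name for s in strategies]
    if len(names) != len(set(names)):
        raise InputError("strategy names must be unique")
    pts = _points(strategies, use_unrounded) + [("__baseline__", 0.0, 0.0)]
    out: dict[str, bool] = {}
    for name, e, c in pts[:-1]:
        out[name] = any(
            (oc <= c and oe >= e and (oc < c or oe > e))
            for oname, oe, oc in pts
            if oname != name
        )
    return out


def eliminate_extended_dominance(
    strategies: Sequence[Strategy], use_unrounded: bool = False
) -> dict[str, bool]:
    """Map name -> weakly dominated?, for strategies with none strictly dominated.

    Iteratively removes any strategy whose ICER versus the next-cheaper
    survivor is >= the ICER of the next-more-effective survivor versus it
    (ICERs recomputed after each removal); the baseline anchors the chain.
    Ties in (cost, effect) keep the lexicographically first name.  The
    survivors are the strict vertices of the lower-left convex hull.
    """
    strict = eliminate_dominated(strategies, use_unrounded)
    if any(strict.values()):
        bad = sorted(n for n, d in strict.items() if d)
        raise InputError(
            f"strictly dominated strategies must be removed first: {bad}"
        )
    weakly: dict[str, bool] = {s.name: False for s in strategies}

    # tie-break exact duplicates on (cost, effect): keep the first name
    seen: dict[tuple[float, float], str] = {}
    for name, e, c in sorted(_points(strategies, use_unrounded)):
        key = (c, e)
        if key in seen:
            weakly[name] = True
        else:
            seen[key] = name

    chain = sorted(
        (p for p in _points(strategies, use_unrounded) if not weakly[p[0]]),
        key=lambda p: (p[2], p[1], p[0]),
    )
    chain.insert(0, ("__baseline__", 0.0, 0.0))
    while True:
        if len(chain) <= 2:
            break
        icers = [
            (chain[i][2] - chain[i - 1][2]) / (chain[i][1] - chain[i - 1][1])
            for i in range(1, len(chain))
        ]
        offender = next(
            (i for i in range(len(icers) - 1) if icers[i] >= icers[i + 1]), None
        )
        if offender is None:
            break
        weakly[chain[offender + 1][0]] = True
        del chain[offender + 1]
    return weakly


def build_frontier(
    strategies: Sequence[Strategy], use_unrounded: bool = False
) -> FrontierResult:
    """Full dominance analysis: labels for every strategy plus the ICER ladder."""
    strict = eliminate_dominated(strategies, use_unrounded)
    survivors = [s for s in strategies if not strict[s.name]]
    weakly = eliminate_extended_dominance(survivors, use_unrounded) if survivors else {}
    frontier = sorted(
        (s for s in survivors if not weakly[s.name]),
        key=lambda s: (s.cost, s.effect_value(use_unrounded), s.name),
    )
    icers: dict[str, float] = {}
    previous = _ORIGIN
    for s in frontier:
        icers[s.name] = pairwise_icer(s, previous, use_unrounded)
        previous = s
    entries = []
    for s in sorted(
        strategies, key=lambda s: (s.cost, s.effect_value(use_unrounded), s.name)
    ):
        if strict[s.name]:
            label = DOMINATED
        elif weakly[s.name]:
            label = WEAKLY_DOMINATED
        else:
            label = NON_DOMINATED
        entries.append(
            FrontierEntry(strategy=s, label=label, icer=icers.get(s.name))
        )
    return FrontierResult(entries=tuple(entries))
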