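"""Readers/writers, packaged fixtures, run configuration and the pipeline.

All tables are comma-separated UTF-8 text with "." decimals; lines starting
with ``#`` are comments (currency columns state their units there).
Packaged fixtures carry SHA-256 checksums verified at load time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .cea import Strategy, build_frontier
from .choice_model import (
    AttributeLevel,
    CoefficientSet,
    InputError,
    Scenario,
    UptakeDelta,
)
from .costing import ConfigurationError, CostConfig, CostLine
from .sensitivity import ScenarioEvaluation, SensitivitySpec, evaluate_scenarios, run_sensitivity
from .uptake import ClinicProfile

__all__ = [
    "IntegrityError",
    "FixtureBundle",
    "RunConfig",
    "read_coefficients",
    "read_clinic_profiles",
    "read_cost_workbook",
    "read_uptake_table",
    "read_strategy_table",
    "strategies_from_table",
    "scenario_from_key",
    "deltas_from_uptake_table",
    "load_fixtures",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger("dce_cea")

_DATA = resources.files("dce_cea") / "data"


class IntegrityError(RuntimeError):
    """Raised when a packaged fixture fails its checksum."""


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


# ---------------------------------------------------------------- readers


def read_coefficients(
    path, baseline: Mapping[str, str] | None = None
) -> CoefficientSet:
    """Coefficient table: columns attribute, level, coefficient, std_error,
    modifiable (true/false)."""
    df = _read_csv(path)
    required = {"attribute", "level", "coefficient", "std_error", "modifiable"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"coefficient table {path} lacks column(s) {sorted(missing)}")
    levels = [
        AttributeLevel(
            attribute=str(r.attribute),
            level=str(r.level),
            coefficient=float(r.coefficient),
            std_error=float(r.std_error),
            modifiable=str(r.modifiable).strip().lower() in {"true", "1", "yes"},
        )
        for r in df.itertuples()
    ]
    return CoefficientSet(levels, baseline=baseline)


def read_clinic_profiles(path) -> dict[str, ClinicProfile]:
    df = _read_csv(path)
    return {
        str(r.clinic): ClinicProfile(
            clinic_name=str(r.clinic),
            baseline_adolescents_per_month=int(r.baseline_adolescents_per_month),
            baseline_uptake_share_pct=float(r.baseline_uptake_share_pct),
            total_monthly_headcount=int(r.total_monthly_headcount),
        )
        for r in df.itertuples()
    }


def _parse_params(raw) -> dict[str, str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return {}
    out: dict[str, str] = {}
    for pair in str(raw).split(";"):
        if "=" not in pair:
            raise ConfigurationError(f"malformed param {pair!r} (expected name=value)")
        name, value = pair.split("=", 1)
        out[name.strip()] = value.strip()
    return out


def read_cost_workbook(path) -> list[CostLine]:
    df = _read_csv(path)
    return [
        CostLine(
            category=str(r.category),
            monthly_amount_zar=float(r.monthly_amount_zar),
            kind=str(r.allocation_kind),
            params=_parse_params(getattr(r, "params", None)),
        )
        for r in df.itertuples()
    ]


def read_uptake_table(path) -> pd.DataFrame:
    """Scenario-level deltas/CIs (the published uptake projection table)."""
    return _read_csv(path)


def read_strategy_table(path) -> pd.DataFrame:
    """Per-clinic published cost-effectiveness table."""
    return _read_csv(path)


def scenario_from_key(key: str) -> Scenario:
    """Build a Scenario from a '+'-joined attribute key like 'food+wifi'."""
    attrs = tuple(sorted(str(key).split("+")))
    return Scenario(name=str(key), switched=tuple((a, a) for a in attrs))


def strategies_from_table(df: pd.DataFrame) -> list[Strategy]:
    """Strategies (effect, cost) from a published-style table."""
    return [
        Strategy(
            name=str(r.scenario),
            effect=float(r.additional_per_month),
            cost=float(r.total_cost_usd),
        )
        for r in df.itertuples()
    ]


def deltas_from_uptake_table(df: pd.DataFrame) -> dict[str, UptakeDelta]:
    return {
        str(r.scenario): UptakeDelta(
            delta_pp=float(r.delta_pp),
            se_pp=float(r.se),
            ci_low_pp=float(r.ci_low_pp),
            ci_high_pp=float(r.ci_high_pp),
        )
        for r in df.itertuples()
    }


# -------------------------------------------------------------- fixtures


@dataclass(frozen=True)
class FixtureBundle:
    """The packaged published tables, parsed."""

    coefficients: CoefficientSet
    uptake: pd.DataFrame
    profiles: dict[str, ClinicProfile]
    clinic_a: pd.DataFrame
    clinic_b: pd.DataFrame
    sensitivity_a: pd.DataFrame
    sensitivity_b: pd.DataFrame
    cost_workbook_b: list[CostLine]


def _verify_checksums() -> None:
    recorded = json.loads((_DATA / "checksums.json").read_text())
    for name, expected in recorded.items():
        digest = hashlib.sha256((_DATA / name).read_bytes()).hexdigest()
        if digest != expected:
            raise IntegrityError(
                f"packaged fixture {name!r} fails its checksum "
                f"(got {digest[:12]}..., expected {expected[:12]}...)"
            )


def load_fixtures() -> FixtureBundle:
    """Load (and checksum-verify) every packaged fixture table."""
    _verify_checksums()
    return FixtureBundle(
        coefficients=read_coefficients(_DATA / "coefficients.csv"),
        uptake=read_uptake_table(_DATA / "table1_uptake.csv"),
        profiles=read_clinic_profiles(_DATA / "clinic_profiles.csv"),
        clinic_a=read_strategy_table(_DATA / "table2_clinic_a.csv"),
        clinic_b=read_strategy_table(_DATA / "table3_clinic_b.csv"),
        sensitivity_a=read_strategy_table(_DATA / "table_a3_clinic_a.csv"),
        sensitivity_b=read_strategy_table(_DATA / "table_a4_clinic_b.csv"),
        cost_workbook_b=read_cost_workbook(_DATA / "cost_workbook_clinic_b.csv"),
    )


# ---------------------------------------------------------------- config


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, recorded in the run log."""

    coefficient_table: str | None = None
    uptake_table: str | None = None
    clinic_profile: str | None = None
    clinic: str = "Clinic B"
    cost_workbook: str | None = None
    exchange_rate: float = 14.0
    ci_z: float = 1.959964
    afternoon_hours_fraction: float = 0.016
    room_share: float = 0.015
    sensitivity_bound: str = "lower"
    floor_one: bool = False
    unrounded_effects: bool = False
    output_dir: str = "out"
    seed: int = 0

    def cost_config(self) -> CostConfig:
        return CostConfig(
            exchange_rate=self.exchange_rate,
            afternoon_hours_fraction=self.afternoon_hours_fraction,
            room_share=self.room_share,
        )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known - {"rounding"}
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    raw.pop("rounding", None)
    return RunConfig(**raw)


# --------------------------------------------------------------- pipeline


def _json_ready(value):
    if isinstance(value, dict):
        return {k: _json_ready(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_json_ready(v) for v in value]
    if isinstance(value, float) and pd.isna(value):
        return None
    return value


def _evaluation_report(evaluation: ScenarioEvaluation) -> dict:
    table = evaluation.table()
    return {
        "strategies": _json_ready(table.to_dict(orient="records")),
        "frontier": [
            {"strategy": e.strategy.name, "icer_usd": e.icer}
            for e in evaluation.frontier.frontier
        ],
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Uptake -> costing -> frontier -> sensitivity, written to output_dir.

    Scenario deltas come from ``uptake_table`` if given (published deltas),
    otherwise from the logit translation of ``coefficient_table``. Outputs:
    a per-clinic frontier table (CSV), a sensitivity table at the
    configured CI bound, a machine-readable ``report.json`` with
    full-precision values, and ``run.log`` recording every decision flag.
    Partial outputs are removed on error.
    """
    fixtures = load_fixtures()
    for name, path in (
        ("coefficient_table", config.coefficient_table),
        ("uptake_table", config.uptake_table),
        ("clinic_profile", config.clinic_profile),
        ("cost_workbook", config.cost_workbook),
    ):
        if path is not None and not Path(path).exists():
            raise InputError(f"{name} not found: {path}")

    coeffs = (
        read_coefficients(config.coefficient_table)
        if config.coefficient_table
        else fixtures.coefficients
    )
    profiles = (
        read_clinic_profiles(config.clinic_profile)
        if config.clinic_profile
        else fixtures.profiles
    )
    if config.clinic not in profiles:
        raise InputError(
            f"clinic {config.clinic!r} not in profiles {sorted(profiles)}"
        )
    profile = profiles[config.clinic]
    lines = (
        read_cost_workbook(config.cost_workbook)
        if config.cost_workbook
        else fixtures.cost_workbook_b
    )
    uptake_df = (
        read_uptake_table(config.uptake_table)
        if config.uptake_table
        else fixtures.uptake
    )

    from .choice_model import delta_uptake, enumerate_scenarios

    deltas_by_key = deltas_from_uptake_table(uptake_df)
    scenarios = enumerate_scenarios(coeffs, only_modifiable=True)
    deltas: list[UptakeDelta] = []
    keyed_scenarios: list[Scenario] = []
    for scenario in scenarios:
        key = "+".join(sorted(a for a, _ in scenario.switched))
        keyed = Scenario(name=key, switched=scenario.switched)
        if key in deltas_by_key:
            delta = deltas_by_key[key]
        else:
            delta = delta_uptake(keyed, coeffs, profile.baseline_prob, z=config.ci_z)
        keyed_scenarios.append(keyed)
        deltas.append(delta)

    cost_config = config.cost_config()
    floor = 1 if config.floor_one else 0
    base = evaluate_scenarios(
        keyed_scenarios,
        [d.delta_pp for d in deltas],
        profile,
        lines,
        config=cost_config,
        floor=floor,
        use_unrounded=config.unrounded_effects,
    )
    sens = run_sensitivity(
        SensitivitySpec(bound=config.sensitivity_bound, clamp_floor=floor),
        keyed_scenarios,
        deltas,
        profile,
        lines,
        config=cost_config,
        use_unrounded=config.unrounded_effects,
    )

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        flags = {k: v for k, v in asdict(config).items()}
        report = {
            "config": flags,
            "clinic": profile.clinic_name,
            "base_case": _evaluation_report(base),
            "sensitivity": {
                "bound": config.sensitivity_bound,
                **_evaluation_report(sens),
            },
        }
        paths = {
            "frontier": outdir / "frontier.csv",
            "sensitivity": outdir / f"sensitivity_{config.sensitivity_bound}.csv",
            "report": outdir / "report.json",
            "log": outdir / "run.log",
        }
        base.table().to_csv(paths["frontier"], index=False, float_format="%.6f")
        written["frontier"] = paths["frontier"]
        sens.table().to_csv(paths["sensitivity"], index=False, float_format="%.6f")
        written["sensitivity"] = paths["sensitivity"]
        paths["report"].write_text(
            json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n"
        )
        written["report"] = paths["report"]
        log_lines = [
            f"clinic={profile.clinic_name}",
            f"rounding=half_away_from_zero floor={'1' if config.floor_one else '0'}",
            f"exchange_rate={config.exchange_rate} ZAR/USD",
            f"comparator=zero-cost zero-effect baseline",
            f"effects={'unrounded' if config.unrounded_effects else 'rounded'}",
            f"ci_z={config.ci_z} sensitivity_bound={config.sensitivity_bound}",
            f"afternoon_hours_fraction={config.afternoon_hours_fraction} "
            f"room_share={config.room_share}",
            f"seed={config.seed}",
        ]
        paths["log"].write_text("\n".join(log_lines) + "\n")
        written["log"] = paths["log"]
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    for name, path in written.items():
        logger.info("wrote %s -> %s", name, path)
    return written
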