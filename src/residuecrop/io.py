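"""Readers and writers for the package's table and config formats.

Tables are CSV with units declared in the column names (``_mg_per_kg``,
``_kg`` ...); silent unit coercion is forbidden — a reader either finds
a column with a unit it knows how to normalize or raises.  Configs are
YAML (or JSON) and validated against an explicit schema before use.
Every writer can attach a run manifest recording the command, inputs,
seed and package version that produced the file.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .dissipation import DissipationFit, ResidueObservation, ResidueSeries
from .errors import ValidationError
from .risk import PesticideToxProfile, PopulationGroup, ResidueSummary
from .uptake import Compartment, ModelParameterization, SimulationResult

__all__ = [
    "read_residue_table",
    "write_residue_table",
    "read_population_table",
    "read_tox_profile",
    "read_parameterization",
    "write_parameterization",
    "read_residue_summary",
    "write_residue_summary",
    "write_fit_report",
    "write_simulation_table",
    "RunManifest",
    "write_manifest",
]

_RESIDUE_COLUMNS = (
    "site_id",
    "matrix",
    "replicate_id",
    "time_days",
    "concentration_mg_per_kg",
    "censored",
    "loq_mg_per_kg",
)

#: Concentration units normalizable to mg/kg: suffix -> factor.
_CONC_UNITS = {"mg_per_kg": 1.0, "ug_per_kg": 1e-3}


def _concentration_column(columns: Iterable[str], stem: str) -> tuple[str, float]:
    """Find ``<stem>_<unit>`` among columns; return (name, factor to mg/kg)."""
    for unit, factor in _CONC_UNITS.items():
        name = f"{stem}_{unit}"
        if name in columns:
            return name, factor
    raise ValidationError(
        f"no column {stem!r} with a declared unit "
        f"({', '.join(f'{stem}_{u}' for u in _CONC_UNITS)}) found"
    )


def read_residue_table(path: str | Path) -> list[ResidueSeries]:
    """Read a residue CSV into series grouped by site x matrix x replicate.

    The header must declare units (``concentration_mg_per_kg`` or
    ``concentration_ug_per_kg``; same for the LOQ column); values are
    normalized to mg/kg on read.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"residue table not found: {path}")
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"residue table is empty: {path}") from None
    if table.empty:
        raise ValidationError(f"residue table is empty: {path}")
    conc_col, conc_factor = _concentration_column(table.columns, "concentration")
    loq_col, loq_factor = _concentration_column(table.columns, "loq")
    for required in ("site_id", "matrix", "time_days", "censored"):
        if required not in table.columns:
            raise ValidationError(f"missing required column {required!r} in {path}")

    problems = []
    for idx, row in table.iterrows():
        if row["time_days"] < 0 or not math.isfinite(row["time_days"]):
            problems.append(f"row {idx}: bad time_days {row['time_days']!r}")
        if row[conc_col] < 0 or not math.isfinite(row[conc_col]):
            problems.append(f"row {idx}: bad {conc_col} {row[conc_col]!r}")
        if not row[loq_col] > 0:
            problems.append(f"row {idx}: bad {loq_col} {row[loq_col]!r}")
        if row["censored"] not in (0, 1, True, False):
            problems.append(f"row {idx}: censored must be 0/1, got {row['censored']!r}")
    if problems:
        raise ValidationError(f"schema errors in {path}", problems)

    series = []
    group_cols = ["site_id", "matrix"]
    has_rep = "replicate_id" in table.columns
    if has_rep:
        group_cols.append("replicate_id")
    for key, sub in table.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        observations = [
            ResidueObservation(
                time_days=float(r["time_days"]),
                concentration=float(r[conc_col]) * conc_factor,
                censored=bool(r["censored"]),
                loq=float(r[loq_col]) * loq_factor,
            )
            for _, r in sub.iterrows()
        ]
        series.append(
            ResidueSeries(
                site_id=str(key[0]),
                matrix=str(key[1]),
                observations=observations,
                replicate_id=str(key[2]) if has_rep else None,
            )
        )
    return series


def write_residue_table(series_list: Sequence[ResidueSeries], path: str | Path) -> None:
    """Write series back to the canonical residue CSV dialect."""
    rows = []
    for s in series_list:
        for o in s.observations:
            rows.append(
                {
                    "site_id": s.site_id,
                    "matrix": s.matrix,
                    "replicate_id": s.replicate_id if s.replicate_id is not None else "",
                    "time_days": o.time_days,
                    "concentration_mg_per_kg": o.concentration,
                    "censored": int(o.censored),
                    "loq_mg_per_kg": o.loq,
                }
            )
    pd.DataFrame(rows, columns=list(_RESIDUE_COLUMNS)).to_csv(path, index=False)


def _optional_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"expected a number, got {value!r}") from None
    return None if math.isnan(f) else f


def read_population_table(path: str | Path) -> list[PopulationGroup]:
    """Read a population diet CSV: group, body_weight_kg, intake_kg_day,
    lp_kg and optional ue_kg / v columns (units in the names)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"population table not found: {path}")
    table = pd.read_csv(path)
    for required in ("group", "body_weight_kg", "lp_kg"):
        if required not in table.columns:
            raise ValidationError(f"missing required column {required!r} in {path}")
    groups = []
    for _, row in table.iterrows():
        groups.append(
            PopulationGroup(
                name=str(row["group"]),
                body_weight_kg=float(row["body_weight_kg"]),
                daily_intake_kg=_optional_float(row.get("intake_kg_day")),
                large_portion_kg=float(row["lp_kg"]),
                unit_weight_kg=_optional_float(row.get("ue_kg")),
                variability_factor=_optional_float(row.get("v")),
            )
        )
    return groups


def read_tox_profile(path: str | Path) -> PesticideToxProfile:
    """Read a toxicological profile from YAML/JSON.

    Keys: name, adi_mg_per_kg_bw_day, arfd_mg_per_kg_bw (optional),
    mrl_mg_per_kg (optional), loq_mg_per_kg.
    """
    data = _load_structured(path)
    try:
        return PesticideToxProfile(
            name=str(data["name"]),
            adi=float(data["adi_mg_per_kg_bw_day"]),
            arfd=_optional_float(data.get("arfd_mg_per_kg_bw")),
            mrl=_optional_float(data.get("mrl_mg_per_kg")),
            loq=float(data.get("loq_mg_per_kg", 0.01)),
        )
    except KeyError as exc:
        raise ValidationError(f"tox profile missing key {exc}") from None


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


_PARAM_SECTIONS = ("pesticide", "processes", "application", "crop")


def read_parameterization(path: str | Path) -> ModelParameterization:
    """Read a model parameterization YAML and validate it.

    Sections: ``pesticide`` (name, log_kow), ``processes``
    (degradation, transfers, dilution; day^-1), ``application``
    (dose_g_per_ha, split) and ``crop`` (biomass kg m^-2, harvest_day).
    """
    data = _load_structured(path)
    missing = [s for s in _PARAM_SECTIONS if s not in data]
    if missing:
        raise ValidationError(f"parameterization missing sections: {missing}")
    processes = data["processes"]
    transfers = {}
    for edge, rate in (processes.get("transfers") or {}).items():
        try:
            a, b = str(edge).split("->")
        except ValueError:
            raise ValidationError(
                f"transfer edge {edge!r} must be written 'from->to'"
            ) from None
        transfers[(Compartment(a.strip()), Compartment(b.strip()))] = float(rate)
    params = ModelParameterization(
        name=str(data["pesticide"].get("name", "unnamed")),
        log_kow=_optional_float(data["pesticide"].get("log_kow")),
        degradation_rate={
            Compartment(c): float(r)
            for c, r in (processes.get("degradation") or {}).items()
        },
        transfer_rate=transfers,
        dilution_rate={
            Compartment(c): float(r)
            for c, r in (processes.get("dilution") or {}).items()
        },
        biomass={
            Compartment(c): float(v)
            for c, v in (data["crop"].get("biomass") or {}).items()
        },
        applied_dose_g_per_ha=float(data["application"]["dose_g_per_ha"]),
        application_split={
            Compartment(c): float(f)
            for c, f in (data["application"].get("split") or {}).items()
        },
        harvest_day=float(data["crop"].get("harvest_day", 63.0)),
    )
    return params.validate()


def write_parameterization(params: ModelParameterization, path: str | Path) -> None:
    """Write a parameterization to the YAML schema ``read_parameterization``
    consumes (round-trip safe)."""
    data = {
        "pesticide": {"name": params.name, "log_kow": params.log_kow},
        "processes": {
            "degradation": {c.value: r for c, r in params.degradation_rate.items()},
            "transfers": {
                f"{a.value}->{b.value}": r for (a, b), r in params.transfer_rate.items()
            },
            "dilution": {c.value: r for c, r in params.dilution_rate.items()},
        },
        "application": {
            "dose_g_per_ha": params.applied_dose_g_per_ha,
            "split": {c.value: f for c, f in params.application_split.items()},
        },
        "crop": {
            "biomass": {c.value: v for c, v in params.biomass.items()},
            "harvest_day": params.harvest_day,
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_residue_summary(path: str | Path) -> ResidueSummary:
    """Read an STMR/HR summary JSON (mg/kg, or µg/kg when declared)."""
    data = _load_structured(path)
    unit = str(data.get("unit", "mg_per_kg"))
    if unit not in _CONC_UNITS:
        raise ValidationError(f"unknown residue unit {unit!r}")
    factor = _CONC_UNITS[unit]
    try:
        return ResidueSummary(
            stmr=float(data["stmr"]) * factor,
            hr=float(data["hr"]) * factor,
            source=str(data.get("source", "field")),
            censored_at_loq=bool(data.get("censored_at_loq", False)),
        )
    except KeyError as exc:
        raise ValidationError(f"residue summary missing key {exc}") from None


def write_residue_summary(summary: ResidueSummary, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "stmr": summary.stmr,
                "hr": summary.hr,
                "unit": "mg_per_kg",
                "source": summary.source,
                "censored_at_loq": summary.censored_at_loq,
            },
            indent=2,
        )
    )


def write_fit_report(
    fits: dict[str, DissipationFit], path: str | Path
) -> None:
    """Write per-series fit results as JSON keyed by series label."""
    Path(path).write_text(
        json.dumps(
            {
                label: {
                    "c0_mg_per_kg": f.c0,
                    "k_per_day": f.k,
                    "half_life_days": f.half_life_days,
                    "r_squared": f.r_squared,
                    "n_used": f.n_used,
                    "n_censored_excluded": f.n_censored_excluded,
                    "policy": f.policy,
                }
                for label, f in fits.items()
            },
            indent=2,
            sort_keys=True,
        )
    )


def write_simulation_table(sim: SimulationResult, path: str | Path) -> None:
    """Tidy CSV of (time_days, compartment, mass_per_applied[, source])."""
    rows = []
    for i, label in enumerate(sim.labels):
        for j, t in enumerate(sim.time_grid):
            rows.append(
                {
                    "time_days": t,
                    "compartment": label,
                    "mass_per_applied": sim.mass[i, j],
                }
            )
    table = pd.DataFrame(rows)
    if sim.source_decomposition:
        extra = []
        for source, mass in sim.source_decomposition.items():
            for i, label in enumerate(sim.labels):
                for j, t in enumerate(sim.time_grid):
                    extra.append(
                        {
                            "time_days": t,
                            "compartment": label,
                            "mass_per_applied": mass[i, j],
                            "source": source.value,
                        }
                    )
        table["source"] = "all"
        table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)
    table.to_csv(path, index=False)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    config_paths: tuple[str, ...] = ()
    seed: int | None = None
    tool_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )


def write_manifest(manifest: RunManifest, output_path: str | Path) -> Path:
    """Write ``<output>.manifest.json`` next to an output file."""
    target = Path(str(output_path) + ".manifest.json")
    target.write_text(json.dumps(asdict(manifest), indent=2))
    return target
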