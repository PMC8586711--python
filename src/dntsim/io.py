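"""Config file format, result serialization, report rendering and run manifests.

Site configs serialize to YAML or JSON (YAML is a superset here; both parse through
the same loader) under a versioned schema with top-level keys ``schema_version``,
``site``, ``p_ems``, ``arrivals``, ``baseline_flags``, ``prep_in_imaging_variant`` and
``activities``. Results are CSV: desk-scale data, diff-friendly. Serialized minutes
are rounded to 3 decimals; all statistics are computed at full precision first.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone

import pandas as pd
import yaml

from .arrivals import ArrivalSchedule
from .distributions import DurationDistribution
from .pathway import Activity, ConfigError, SiteConfig
from .stats import ComparisonResult, SummaryStats

__all__ = ["read_config", "write_config", "config_to_dict", "config_from_dict",
           "records_to_dataframe", "render_report", "RunManifest", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class SchemaError(ConfigError):
    """Config file violates the documented schema; message names the key path."""


# -- distribution <-> dict -------------------------------------------------------------

def _dist_to_dict(d: DurationDistribution) -> dict:
    out = {"family": d.family, "params": list(d.params)}
    if d.lower_bound:
        out["lower_bound"] = d.lower_bound
    if d.provenance != "unspecified":
        out["provenance"] = d.provenance
    return out


def _dist_from_dict(obj, path: str) -> DurationDistribution:
    if not isinstance(obj, dict):
        raise SchemaError(f"{path}: expected a mapping with family/params")
    for key in ("family", "params"):
        if key not in obj:
            raise SchemaError(f"{path}.{key}: missing required key")
    params = obj["params"]
    if not isinstance(params, (list, tuple)):
        raise SchemaError(f"{path}.params: expected a list of numbers")
    for i, p in enumerate(params):
        if not isinstance(p, (int, float)) or isinstance(p, bool):
            raise SchemaError(f"{path}.params[{i}]: expected a number, got {p!r}")
    try:
        return DurationDistribution(obj["family"], tuple(params),
                                    lower_bound=float(obj.get("lower_bound", 0.0)),
                                    provenance=str(obj.get("provenance",
                                                           "unspecified")))
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# -- config <-> dict -------------------------------------------------------------------

def config_to_dict(config: SiteConfig) -> dict:
    acts = []
    for a in config.activities:
        entry = {
            "id": a.id, "phase": a.phase, "applies_to": a.applies_to,
            "hours": a.hours, "predecessors": list(a.predecessors),
            "duration_regular": _dist_to_dict(a.duration_regular),
        }
        if a.duration_out_of_hours is not None:
            entry["duration_out_of_hours"] = _dist_to_dict(a.duration_out_of_hours)
        if a.role:
            entry["role"] = a.role
        if a.label:
            entry["label"] = a.label
        acts.append(entry)
    return {
        "schema_version": SCHEMA_VERSION,
        "site": config.site_id,
        "p_ems": config.p_ems,
        "arrivals": {"block_rates": list(config.schedule.block_rates),
                     "scale": config.schedule.scale},
        "baseline_flags": sorted(config.baseline_flags),
        "prep_in_imaging_variant": _dist_to_dict(config.tpa_prep_in_imaging_variant),
        "activities": acts,
    }


def config_from_dict(obj: dict) -> SiteConfig:
    if not isinstance(obj, dict):
        raise SchemaError("top level: expected a mapping")
    version = obj.get("schema_version", SCHEMA_VERSION)
    if int(version) != SCHEMA_VERSION:
        raise SchemaError(f"schema_version: file has major version {version}, "
                          f"this package reads {SCHEMA_VERSION}")
    for key in ("site", "arrivals", "activities", "prep_in_imaging_variant"):
        if key not in obj:
            raise SchemaError(f"{key}: missing required key")

    arr = obj["arrivals"]
    if not isinstance(arr, dict) or "block_rates" not in arr:
        raise SchemaError("arrivals.block_rates: missing required key")
    rates = arr["block_rates"]
    for i, r in enumerate(rates):
        if not isinstance(r, (int, float)) or isinstance(r, bool):
            raise SchemaError(f"arrivals.block_rates[{i}]: expected a number, "
                              f"got {r!r}")
    schedule = ArrivalSchedule(tuple(rates), scale=float(arr.get("scale", 1.0)))

    activities = []
    for i, entry in enumerate(obj["activities"]):
        path = f"activities[{i}]"
        if not isinstance(entry, dict) or "id" not in entry:
            raise SchemaError(f"{path}.id: missing required key")
        ooh = entry.get("duration_out_of_hours")
        try:
            activities.append(Activity(
                id=str(entry["id"]),
                phase=str(entry.get("phase", "C")),
                duration_regular=_dist_from_dict(entry.get("duration_regular"),
                                                 f"{path}.duration_regular"),
                duration_out_of_hours=(None if ooh is None else
                                       _dist_from_dict(ooh,
                                                       f"{path}.duration_out_of_hours")),
                applies_to=str(entry.get("applies_to", "both")),
                hours=str(entry.get("hours", "both")),
                predecessors=tuple(entry.get("predecessors", ())),
                role=entry.get("role"),
                label=str(entry.get("label", "")),
            ))
        except ConfigError as exc:
            raise SchemaError(f"{path}: {exc}") from exc

    return SiteConfig(
        site_id=str(obj["site"]),
        activities=tuple(activities),
        schedule=schedule,
        tpa_prep_in_imaging_variant=_dist_from_dict(
            obj["prep_in_imaging_variant"], "prep_in_imaging_variant"),
        p_ems=float(obj.get("p_ems", 0.80)),
        baseline_flags=frozenset(obj.get("baseline_flags", ())),
    )


def read_config(path) -> SiteConfig:
    with open(path) as fh:
        text = fh.read()
    try:
        obj = yaml.safe_load(text)  # YAML loader also accepts JSON
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: cannot parse as YAML or JSON: {exc}") from exc
    return config_from_dict(obj)


def write_config(config: SiteConfig, path) -> None:
    obj = config_to_dict(config)
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(obj, fh, indent=2)
        else:
            yaml.safe_dump(obj, fh, sort_keys=False)


# -- results ---------------------------------------------------------------------------

def records_to_dataframe(replications) -> pd.DataFrame:
    """Patient log as a flat table, one row per patient."""
    rows = []
    for rep in replications:
        for r in rep:
            row = {
                "patient_id": r.patient_id, "replication_id": r.replication_id,
                "pathway": r.pathway, "hours_class": r.hours_class,
                "door_minute": round(r.door_time, 3),
                "needle_minute": round(r.needle_time, 3),
                "dnt_minutes": round(r.dnt, 3),
            }
            for aid, start, fin in r.activity_log:
                row[f"{aid}_start"] = round(start, 3)
                row[f"{aid}_finish"] = round(fin, 3)
            rows.append(row)
    return pd.DataFrame(rows)


def render_report(site_id: str, baseline: SummaryStats,
                  scenario_results: dict[str, tuple[SummaryStats,
                                                    ComparisonResult | None]],
                  baseline_noops: set[str] | None = None) -> pd.DataFrame:
    """Summary table mirroring the published layout: one row per scenario.

    ``scenario_results`` maps scenario labels to (summary, comparison); a comparison
    of ``None`` together with membership in ``baseline_noops`` marks a process change
    the site already practices, rendered as "Current baseline".
    """
    baseline_noops = baseline_noops or set()
    rows = [{
        "site": site_id, "scenario": "baseline", "status": "",
        "n": baseline.n, "median": round(baseline.median, 3),
        "q25": round(baseline.q25, 3), "q75": round(baseline.q75, 3),
        "p90": round(baseline.p90, 3), "mwu_p": None,
        "median_reduction_pct": None, "ci_low": None, "ci_high": None,
    }]
    for label, (summary, cmp_res) in scenario_results.items():
        if label in baseline_noops:
            rows.append({"site": site_id, "scenario": label,
                         "status": "Current baseline",
                         "n": baseline.n, "median": round(baseline.median, 3),
                         "q25": round(baseline.q25, 3),
                         "q75": round(baseline.q75, 3),
                         "p90": round(baseline.p90, 3), "mwu_p": None,
                         "median_reduction_pct": None,
                         "ci_low": None, "ci_high": None})
            continue
        rows.append({
            "site": site_id, "scenario": label, "status": "",
            "n": summary.n, "median": round(summary.median, 3),
            "q25": round(summary.q25, 3), "q75": round(summary.q75, 3),
            "p90": round(summary.p90, 3),
            "mwu_p": None if cmp_res is None else cmp_res.mwu_p,
            "median_reduction_pct": (None if cmp_res is None
                                     else round(cmp_res.median_reduction_pct, 3)),
            "ci_low": (None if cmp_res is None
                       else round(cmp_res.median_ci95[0], 3)),
            "ci_high": (None if cmp_res is None
                        else round(cmp_res.median_ci95[1], 3)),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run byte-identically."""

    config_path: str
    config_sha256: str
    scenario: str
    n_reps: int
    horizon_days: int
    seed: int
    package_version: str
    created_utc: str

    @classmethod
    def create(cls, config_path, scenario: str, n_reps: int, horizon_days: int,
               seed: int) -> "RunManifest":
        from . import __version__
        with open(config_path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        return cls(config_path=str(config_path), config_sha256=digest,
                   scenario=scenario, n_reps=n_reps, horizon_days=horizon_days,
                   seed=seed, package_version=__version__,
                   created_utc=datetime.now(timezone.utc).isoformat())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
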