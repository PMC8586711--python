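"""Domain model of the intra-hospital thrombolysis pathway.

The treatment process is a stochastic activity network: a directed acyclic graph of
activities between the patient's arrival at the hospital door and the start of the tPA
bolus (the "needle"). Activities belong to four phases — A: pre-arrival (hospital work
done before an EMS patient arrives, enabled by paramedic pre-notification), B: arrival,
C: imaging and treatment decision, D: treatment — and may apply to one arrival pathway
(EMS or private vehicle) or both, and to one hours class (Monday–Friday 08:00–16:00
"regular" vs everything else "out of hours") or both.

A :class:`SiteConfig` bundles the activity set with the site's arrival schedule, the
EMS/PV pathway mix, the Table-style baseline flags (which improvement scenarios a site
already practices) and the in-imaging tPA-prep variant used by scenario P2.

:func:`critical_path` is the deterministic longest-path oracle: with fixed durations the
door-to-needle time equals the longest door-to-bolus path, which the event engine must
reproduce exactly when all duration laws are constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from graphlib import CycleError, TopologicalSorter

from .arrivals import ArrivalSchedule
from .distributions import DurationDistribution

__all__ = [
    "Activity",
    "SiteConfig",
    "validate_config",
    "ConfigError",
    "applicable_activities",
    "effective_predecessors",
    "critical_path",
    "PATHWAYS",
    "HOURS_CLASSES",
]

PATHWAYS = ("EMS", "PV")
HOURS_CLASSES = ("regular", "out_of_hours")
PHASES = ("A", "B", "C", "D")

ROLES = frozenset({
    "transfer_to_ed_bay", "registration", "travel_to_imaging", "ncct", "cta",
    "labs", "neuro_assessment", "interpretation", "decision", "tpa_prep",
    "travel_imaging_to_ed", "bolus", "ct_callin_delay", "triage", "recognition",
    "protocol_activation", "team_activation", "pre_notification",
})


class ConfigError(ValueError):
    """Raised when a configuration cannot be used by the engine."""


@dataclass(frozen=True)
class Activity:
    """One node of the treatment activity graph."""

    id: str
    phase: str  # A | B | C | D
    duration_regular: DurationDistribution
    duration_out_of_hours: DurationDistribution | None = None  # None -> same as regular
    applies_to: str = "both"  # EMS | PV | both
    hours: str = "both"  # regular | out | both
    predecessors: tuple[str, ...] = ()
    role: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ConfigError(f"{self.id}: phase must be one of {PHASES}")
        if self.applies_to not in ("EMS", "PV", "both"):
            raise ConfigError(f"{self.id}: applies_to must be EMS, PV or both")
        if self.hours not in ("regular", "out", "both"):
            raise ConfigError(f"{self.id}: hours must be regular, out or both")
        if self.role is not None and self.role not in ROLES:
            raise ConfigError(f"{self.id}: unknown role {self.role!r}")
        object.__setattr__(self, "predecessors", tuple(self.predecessors))

    def duration(self, hours_class: str) -> DurationDistribution:
        if hours_class == "out_of_hours" and self.duration_out_of_hours is not None:
            return self.duration_out_of_hours
        return self.duration_regular

    def applies(self, pathway: str, hours_class: str) -> bool:
        if self.applies_to != "both" and self.applies_to != pathway:
            return False
        if self.hours == "regular" and hours_class != "regular":
            return False
        if self.hours == "out" and hours_class != "out_of_hours":
            return False
        return True


@dataclass(frozen=True)
class SiteConfig:
    """A whole per-site model: activity graph, arrivals, mix and baseline flags."""

    site_id: str
    activities: tuple[Activity, ...]
    schedule: ArrivalSchedule
    tpa_prep_in_imaging_variant: DurationDistribution
    p_ems: float = 0.80
    baseline_flags: frozenset[str] = frozenset()
    applied_scenarios: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "activities", tuple(self.activities))
        object.__setattr__(self, "baseline_flags", frozenset(self.baseline_flags))
        object.__setattr__(self, "applied_scenarios", frozenset(self.applied_scenarios))

    def activity(self, act_id: str) -> Activity:
        for a in self.activities:
            if a.id == act_id:
                return a
        raise KeyError(act_id)

    def by_role(self, role: str) -> tuple[Activity, ...]:
        return tuple(a for a in self.activities if a.role == role)

    @property
    def arrival_scale(self) -> float:
        return self.schedule.scale


# -- graph projection ------------------------------------------------------------------

def applicable_activities(config: SiteConfig, pathway: str,
                          hours_class: str) -> tuple[Activity, ...]:
    """Post-door activities applicable to a (pathway, hours-class) episode.

    Phase-A activities are excluded: for EMS patients they run before the door
    (pre-notification is always received, so they contribute zero post-door time) and
    for PV patients they do not exist at all.
    """
    return tuple(a for a in config.activities
                 if a.phase != "A" and a.applies(pathway, hours_class))


def effective_predecessors(config: SiteConfig, pathway: str,
                           hours_class: str) -> dict[str, frozenset[str]]:
    """Predecessor map of the projected DAG.

    Activities not applicable to the episode (wrong pathway, wrong hours class, or
    phase A) are bypassed transitively: their successors inherit their predecessors.
    """
    applicable = {a.id for a in applicable_activities(config, pathway, hours_class)}
    all_preds = {a.id: a.predecessors for a in config.activities}

    resolved: dict[str, frozenset[str]] = {}

    def resolve(act_id: str, trail: tuple[str, ...]) -> frozenset[str]:
        # set of *applicable* activities reached by following predecessor links
        # through non-applicable nodes
        if act_id in trail:
            raise ConfigError(
                f"predecessor cycle involving {' -> '.join(trail + (act_id,))}")
        out: set[str] = set()
        for p in all_preds.get(act_id, ()):
            if p not in all_preds:
                raise ConfigError(f"{act_id}: unknown predecessor {p!r}")
            if p in applicable:
                out.add(p)
            else:
                out |= resolve(p, trail + (act_id,))
        return frozenset(out)

    for aid in applicable:
        resolved[aid] = resolve(aid, ())
    return resolved


def _topo_order(preds: dict[str, frozenset[str]]) -> list[str]:
    try:
        return list(TopologicalSorter({k: set(v) for k, v in preds.items()}).static_order())
    except CycleError as exc:  # pragma: no cover - validate_config catches first
        raise ConfigError(f"activity graph contains a cycle: {exc}") from exc


# -- validation ------------------------------------------------------------------------

def validate_config(config: SiteConfig) -> list[str]:
    """Every invariant violation, as human-readable strings; empty means usable."""
    report: list[str] = []
    ids = [a.id for a in config.activities]
    seen = set()
    for i in ids:
        if i in seen:
            report.append(f"duplicate activity id {i!r}")
        seen.add(i)
    for a in config.activities:
        for p in a.predecessors:
            if p not in seen:
                report.append(f"{a.id}: predecessor {p!r} does not exist")
    if report:
        return report  # graph-level checks need a well-formed id space

    if not 0.0 < config.p_ems < 1.0:
        report.append(f"p_ems must be in (0, 1), got {config.p_ems}")
    sched_problems = config.schedule.validate()
    report.extend(sched_problems)

    for pathway in PATHWAYS:
        for hours_class in HOURS_CLASSES:
            tag = f"[{pathway}/{hours_class}]"
            try:
                preds = effective_predecessors(config, pathway, hours_class)
            except ConfigError as exc:
                report.append(f"{tag} {exc}")
                continue
            try:
                _topo_order(preds)
            except ConfigError as exc:
                report.append(f"{tag} {exc}")
                continue
            acts = applicable_activities(config, pathway, hours_class)
            for role in ("bolus", "decision", "tpa_prep"):
                n = sum(1 for a in acts if a.role == role)
                if n != 1:
                    report.append(f"{tag} expected exactly one role={role} activity, "
                                  f"found {n}")
    return report


# -- deterministic longest-path oracle -------------------------------------------------

def critical_path(config: SiteConfig, pathway: str, hours_class: str,
                  fixed_durations: dict[str, float]) -> tuple[float, list[str]]:
    """Longest door-to-bolus path with fixed activity durations.

    Returns ``(length, path)`` where ``length`` is the earliest possible start of the
    bolus activity (door-to-needle time) and ``path`` one maximizing chain of activity
    ids ending in the bolus. The bolus's own duration does not count: DNT is measured
    to the *start* of bolus administration. Phase-A activities contribute zero post-door
    time and are excluded from the graph.
    """
    preds = effective_predecessors(config, pathway, hours_class)
    acts = {a.id: a for a in applicable_activities(config, pathway, hours_class)}
    bolus = [a for a in acts.values() if a.role == "bolus"]
    if len(bolus) != 1:
        raise ConfigError(f"expected exactly one bolus activity, found {len(bolus)}")
    bolus_id = bolus[0].id

    missing = [aid for aid in acts if aid != bolus_id and aid not in fixed_durations]
    if missing:
        raise ConfigError(f"missing fixed durations for: {sorted(missing)}")

    finish: dict[str, float] = {}
    argmax: dict[str, str | None] = {}
    for aid in _topo_order(preds):
        best, best_pred = 0.0, None
        for p in preds[aid]:
            if finish[p] > best:
                best, best_pred = finish[p], p
        dur = 0.0 if aid == bolus_id else float(fixed_durations[aid])
        finish[aid] = best + dur
        argmax[aid] = best_pred

    length = finish[bolus_id]
    path: list[str] = []
    node: str | None = bolus_id
    while node is not None:
        path.append(node)
        node = argmax[node]
    path.reverse()
    return length, path
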