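"""Discrete-event core: executes each patient's activity DAG and emits records.

Scheduling is earliest-start over the (pathway, hours-class) projection of the activity
graph: an activity starts at the latest finish of its effective predecessors, and the
first post-door activities start at the later of the door time and the protocol token
becoming free. The hospital can run only one stroke protocol activation at a time, so a
capacity-one token is held from the first post-door activity start until the bolus
start (the needle time) and is granted FIFO by door time. Because that is the only
shared resource, processing patients in door-time order with a single running
``token_free`` clock is exactly equivalent to a full event-calendar simulation.

Randomness is organized as one substream per (base seed, replication, patient index,
activity id), so deleting an activity or scaling a duration in a scenario leaves every
other draw untouched — the common-random-number guarantees (e.g. a scenario can never
increase a patient's DNT) hold exactly, not just in expectation.

The hours class of an episode is fixed at door time and not re-evaluated mid-episode.
Patients whose door time falls inside the horizon always run to completion (no
censoring, no warm-up discard).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .arrivals import assign_pathway, classify_hours, generate_arrivals
from .pathway import (ConfigError, SiteConfig, applicable_activities,
                      effective_predecessors, validate_config)
from .scenarios import ScenarioSpec, apply_scenarios

__all__ = ["PatientRecord", "execute_patient", "run_replication",
           "run_experiment", "dnt_array", "pooled_dnts"]

_ARRIVALS_KEY = 0x0A221
_PATHWAY_KEY = 0x09A77


def _activity_key(act_id: str) -> int:
    return zlib.crc32(act_id.encode("utf-8"))


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient's timestamps from door to needle (minutes)."""

    patient_id: int
    replication_id: int
    door_time: float
    pathway: str  # EMS | PV
    hours_class: str  # regular | out_of_hours
    activity_log: tuple[tuple[str, float, float], ...]  # (id, start, finish)
    needle_time: float

    @property
    def dnt(self) -> float:
        return self.needle_time - self.door_time


class _Plan:
    """Pre-computed projection of a config for one (pathway, hours-class) pair."""

    __slots__ = ("order", "preds", "durations", "bolus_id", "keys", "phase_a")

    def __init__(self, config: SiteConfig, pathway: str, hours_class: str):
        from .pathway import _topo_order  # shared topological sort

        preds = effective_predecessors(config, pathway, hours_class)
        acts = {a.id: a for a in applicable_activities(config, pathway, hours_class)}
        bolus = [a for a in acts.values() if a.role == "bolus"]
        if len(bolus) != 1:
            raise ConfigError("config must contain exactly one bolus activity "
                              f"for {pathway}/{hours_class}")
        self.bolus_id = bolus[0].id
        self.order = _topo_order(preds)
        self.preds = preds
        self.durations = {aid: acts[aid].duration(hours_class) for aid in acts}
        self.keys = {aid: _activity_key(aid) for aid in acts}
        if pathway == "EMS":
            phase_a = [a for a in config.activities
                       if a.phase == "A" and a.applies(pathway, hours_class)]
            self.phase_a = [(a.id, a.duration(hours_class), _activity_key(a.id))
                            for a in phase_a]
        else:
            self.phase_a = []


def _patient_rng(base_seed: int, rep: int, patient_idx: int, key: int):
    return np.random.default_rng([base_seed, rep, patient_idx, key])


def execute_patient(plan: _Plan, patient_id: int, replication_id: int,
                    pathway: str, hours_class: str, door_time: float,
                    token_free: float, base_seed: int) -> tuple[PatientRecord, float]:
    """Run one patient through the projected DAG; returns (record, new token_free)."""
    entry = max(door_time, token_free)
    log: list[tuple[str, float, float]] = []

    # Phase-A work (EMS pre-arrival): logged before the door, zero post-door cost.
    for aid, dist, key in plan.phase_a:
        dur = dist.sample(_patient_rng(base_seed, replication_id, patient_id, key))
        log.append((aid, door_time - dur, door_time))

    finish: dict[str, float] = {}
    for aid in plan.order:
        start = entry
        for p in plan.preds[aid]:
            if finish[p] > start:
                start = finish[p]
        if aid == plan.bolus_id:
            needle_time = start
        dur = plan.durations[aid].sample(
            _patient_rng(base_seed, replication_id, patient_id, plan.keys[aid]))
        finish[aid] = start + dur
        log.append((aid, start, start + dur))

    record = PatientRecord(
        patient_id=patient_id, replication_id=replication_id, door_time=door_time,
        pathway=pathway, hours_class=hours_class, activity_log=tuple(log),
        needle_time=needle_time)
    return record, needle_time


def run_replication(config: SiteConfig, scenario: ScenarioSpec | None,
                    horizon_days: int, seed: int, replication_id: int = 0,
                    independent_arrivals: bool = False) -> list[PatientRecord]:
    """One replication: arrivals over the horizon, every patient run to completion.

    With the default ``independent_arrivals=False`` the arrival stream and pathway
    assignments depend only on (seed, replication), never on the scenario, so scenario
    comparisons share common random numbers.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    cfg = apply_scenarios(config, scenario) if scenario and scenario.codes else config

    arrival_salt = _activity_key(str(scenario)) if (independent_arrivals and scenario) else 0
    arr_rng = np.random.default_rng(
        [seed, replication_id, (_ARRIVALS_KEY + arrival_salt) % (2 ** 31)])
    arrivals = generate_arrivals(cfg.schedule, horizon_days, arr_rng)

    plans = {(pw, hc): _Plan(cfg, pw, hc)
             for pw in ("EMS", "PV") for hc in ("regular", "out_of_hours")}

    records: list[PatientRecord] = []
    token_free = 0.0
    for i, t in enumerate(arrivals):
        pw_rng = _patient_rng(seed, replication_id, i, _PATHWAY_KEY)
        pathway = assign_pathway(pw_rng, cfg.p_ems)
        hours_class = classify_hours(t)
        record, token_free = execute_patient(
            plans[(pathway, hours_class)], i, replication_id, pathway, hours_class,
            float(t), token_free, seed)
        records.append(record)
    return records


def run_experiment(config: SiteConfig, scenario: ScenarioSpec | None = None,
                   n_reps: int = 30, horizon_days: int = 365, base_seed: int = 0,
                   independent_arrivals: bool = False) -> list[list[PatientRecord]]:
    """Replication-indexed patient records; replication r uses substream (seed, r)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [run_replication(config, scenario, horizon_days, base_seed,
                            replication_id=r, independent_arrivals=independent_arrivals)
            for r in range(n_reps)]


def dnt_array(records: list[PatientRecord]) -> np.ndarray:
    return np.array([r.dnt for r in records])


def pooled_dnts(replications: list[list[PatientRecord]]) -> np.ndarray:
    return np.concatenate([dnt_array(r) for r in replications]) \
        if any(len(r) for r in replications) else np.empty(0)
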