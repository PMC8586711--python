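"""Shipped site configurations and calibration utilities.

Three sites are modelled: one urban tertiary centre ("site1") and two rural hospitals
("site2", "site3"). Their structural differences, as the sites describe their own
practice:

* **site1 (urban)** already keeps EMS patients on the stretcher to imaging (P1) and
  pre-registers them (P3); during regular hours it already administers tPA in the
  imaging area, so the imaging-to-ED travel exists only out of hours and the
  regular-hours prep is the in-imaging variant. A neuroradiology/CT service is in
  house around the clock (no call-in delay).
* **site2 (rural)** also practices P1 and P3, but administers tPA in the ED in both
  hours classes (travel back from imaging always present) and has CT technologists
  on call out of hours (a call-in delay before the scan).
* **site3 (rural)** practices none of the process changes: EMS patients are
  transferred to an ED bay, registration happens post-door, tPA is given in the ED,
  and the CT technologist is on call out of hours. Its treatment-decision and
  tPA-prep branches are long and nearly balanced, so reducing either alone merely
  moves the bottleneck — both must shrink before the door-to-needle time does.

The published activity-duration tables (supplementary material) are not shipped with
the paper's main text, so the default configs carry **calibrated stand-in
distributions** (``provenance="calibrated"``): triangular laws for expert-elicited
in-hospital tasks plus a lognormal stroke-recognition delay for walk-in patients,
whose shape ratios were tuned by Monte-Carlo so the shipped baselines and scenario
responses reproduce the published summary behaviour. :func:`load_sm1_distributions`
replaces them with transcribed values (``provenance="SM1"``) when those are available.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

from .arrivals import ArrivalSchedule
from .distributions import (DurationDistribution, constant, lognormal, triangular)
from .engine import run_experiment
from .pathway import Activity, ConfigError, SiteConfig, validate_config
from .stats import pooled_summary

__all__ = [
    "TABLE_BLOCK_RATES",
    "SITE_ARRIVAL_SCALES",
    "default_arrival_schedule",
    "default_site_configs",
    "CalibrationResult",
    "calibrate_global_scale",
    "scale_all_durations",
    "load_sm1_distributions",
]

# Verified hourly arrival rates for the twelve two-hour clock blocks 00-02 .. 22-24,
# identical across days of week (urban-site observations; rural sites use the same
# time-of-day profile at lower volume).
TABLE_BLOCK_RATES = (
    0.00428, 0.00321, 0.00321, 0.00642, 0.01391, 0.01819,
    0.01926, 0.01712, 0.01712, 0.01605, 0.01070, 0.00856,
)

# Annual treated volumes pool to roughly 3021 : 780 : 405 over 30 one-year runs.
SITE_ARRIVAL_SCALES = {
    "site1_urban": 1.0,
    "site2_rural": 780.0 / 3021.0,
    "site3_rural": 405.0 / 3021.0,
}

# Global duration multipliers pinning each shipped baseline median DNT to the
# observed 50.0 / 40.1 / 74.0 minutes (found by calibrate_global_scale and frozen).
SITE_DURATION_SCALES = {
    "site1_urban": 0.987502,
    "site2_rural": 0.825517,
    "site3_rural": 0.943716,
}


def default_arrival_schedule(scale: float = 1.0) -> ArrivalSchedule:
    return ArrivalSchedule(block_rates=TABLE_BLOCK_RATES, scale=scale)


def _tri(a: float, m: float, b: float) -> DurationDistribution:
    return triangular(a, m, b, provenance="calibrated")


def _logn(median: float, sigma: float) -> DurationDistribution:
    return lognormal(median, sigma, provenance="calibrated")


def _common_phase_bcd(d: dict[str, DurationDistribution],
                      site3: bool = False) -> list[Activity]:
    """Imaging/decision/treatment activities shared by all sites (phases C and D)."""
    rural_delay = []
    if "ct_callin_delay" in d:
        rural_delay = [Activity("ct_callin_delay", "C", d["ct_callin_delay"],
                                hours="out", predecessors=("travel_to_imaging",),
                                role="ct_callin_delay",
                                label="CT technologist call-in (out of hours)")]
    travel_out = []
    if "travel_imaging_to_ed" in d:
        travel_out = [Activity("travel_imaging_to_ed", "D",
                               d["travel_imaging_to_ed"],
                               hours=d.get("_travel_out_hours", "both"),
                               predecessors=("decision",),
                               role="travel_imaging_to_ed",
                               label="travel from imaging back to ED")]
    ncct_preds = (("ct_callin_delay", "travel_to_imaging") if rural_delay
                  else ("travel_to_imaging",))
    bolus_preds = (("decision", "tpa_prep", "travel_imaging_to_ed") if travel_out
                   else ("decision", "tpa_prep"))
    return rural_delay + [
        Activity("ncct", "C", d["ncct"], predecessors=ncct_preds,
                 role="ncct", label="non-contrast CT"),
        Activity("cta", "C", d["cta"], predecessors=("ncct",), role="cta",
                 label="CT angiography"),
        Activity("labs", "C", d["labs"], predecessors=("travel_to_imaging",),
                 role="labs", label="blood draw and lab processing"),
        Activity("neuro_assessment", "C", d["neuro_assessment"],
                 predecessors=("travel_to_imaging",), role="neuro_assessment",
                 label="neurological assessment"),
        Activity("interpretation", "C", d["interpretation"],
                 predecessors=("cta",), role="interpretation",
                 label="imaging interpretation"),
        Activity("decision", "C", d["decision"],
                 duration_out_of_hours=d.get("decision_out"),
                 predecessors=("interpretation", "labs", "neuro_assessment"),
                 role="decision", label="treatment decision"),
        Activity("tpa_prep", "D", d["tpa_prep"],
                 duration_out_of_hours=d.get("tpa_prep_out"),
                 predecessors=("interpretation",), role="tpa_prep",
                 label="tPA preparation (drug, weight, dose, pump)"),
    ] + travel_out + [
        Activity("bolus", "D", constant(1.0, provenance="calibrated"),
                 predecessors=bolus_preds,
                 role="bolus", label="tPA bolus administration"),
    ]


def _pv_arrival(d: dict[str, DurationDistribution]) -> list[Activity]:
    return [
        Activity("triage", "B", d["triage"], applies_to="PV",
                 role="triage", label="ED triage"),
        Activity("registration_pv", "B", d["registration_pv"], applies_to="PV",
                 predecessors=("triage",), role="registration",
                 label="ED registration (walk-in)"),
        Activity("recognition", "B", d["recognition"], applies_to="PV",
                 predecessors=("registration_pv",), role="recognition",
                 label="stroke recognition in ED (potential delay)"),
        Activity("protocol_activation", "B", d["protocol_activation"],
                 applies_to="PV", predecessors=("recognition",),
                 role="protocol_activation", label="stroke protocol activation"),
    ]


def _site1_config() -> SiteConfig:
    k = SITE_DURATION_SCALES["site1_urban"]
    d = {
        "triage": _tri(2, 4, 6),
        "registration_pv": _tri(3, 5, 8),
        "recognition": _logn(16.0, 0.95),
        "protocol_activation": _tri(1, 2, 4),
        "ncct": _tri(6, 8, 11),
        "cta": _tri(4, 6, 9),
        "labs": _tri(6, 10, 14),
        "neuro_assessment": _tri(4, 7, 10),
        "interpretation": _tri(4, 6, 9),
        "decision": _tri(6.5, 7.25, 8),
        # regular hours: prep already happens in imaging (partial P2 baseline);
        # out of hours: full ED prep, plus the travel back from imaging.
        "tpa_prep": _tri(9, 12, 15.5),
        "tpa_prep_out": _tri(16.5, 19, 23.5),
        "travel_imaging_to_ed": _tri(7, 7.75, 8.5),
        "_travel_out_hours": "out",
    }
    acts = [
        Activity("pre_notification", "A", _tri(3, 5, 8), applies_to="EMS",
                 role="pre_notification", label="EMS pre-notification received"),
        Activity("registration_ems", "A", _tri(2, 4, 6), applies_to="EMS",
                 role="registration", label="pre-registration (EMS)"),
        Activity("ems_assessment", "B", _tri(3, 4, 6), applies_to="EMS",
                 label="initial assessment on EMS stretcher"),
        *_pv_arrival(d),
        Activity("travel_to_imaging", "B", _tri(4, 6, 8),
                 predecessors=("ems_assessment", "registration_ems",
                               "protocol_activation"),
                 role="travel_to_imaging", label="travel to imaging"),
        *_common_phase_bcd(d),
    ]
    cfg = SiteConfig(
        site_id="site1_urban", activities=tuple(acts),
        schedule=default_arrival_schedule(SITE_ARRIVAL_SCALES["site1_urban"]),
        tpa_prep_in_imaging_variant=d["tpa_prep"],
        baseline_flags=frozenset({"P1", "P3"}))
    return scale_all_durations(cfg, k)


def _site2_config() -> SiteConfig:
    k = SITE_DURATION_SCALES["site2_rural"]
    d = {
        "triage": _tri(2, 4, 6),
        "registration_pv": _tri(3, 5, 7),
        "recognition": _logn(14.0, 0.95),
        "protocol_activation": _tri(1, 2, 4),
        "ct_callin_delay": _tri(2, 6, 12),
        "ncct": _tri(5, 7, 9.5),
        "cta": _tri(3.5, 5, 7),
        "labs": _tri(5, 8, 11.5),
        "neuro_assessment": _tri(3.5, 6, 8.5),
        "interpretation": _tri(3.5, 5, 7),
        "decision": _tri(6.5, 7, 7.5),
        "tpa_prep": _tri(15, 16, 18),
        "travel_imaging_to_ed": _tri(6.5, 7, 7.5),
    }
    acts = [
        Activity("pre_notification", "A", _tri(3, 5, 8), applies_to="EMS",
                 role="pre_notification", label="EMS pre-notification received"),
        Activity("registration_ems", "A", _tri(2, 3.5, 5), applies_to="EMS",
                 role="registration", label="pre-registration (EMS)"),
        Activity("ems_assessment", "B", _tri(2.5, 3.5, 5), applies_to="EMS",
                 label="initial assessment on EMS stretcher"),
        *_pv_arrival(d),
        Activity("travel_to_imaging", "B", _tri(3, 4.5, 6.5),
                 predecessors=("ems_assessment", "registration_ems",
                               "protocol_activation"),
                 role="travel_to_imaging", label="travel to imaging"),
        *_common_phase_bcd(d),
    ]
    cfg = SiteConfig(
        site_id="site2_rural", activities=tuple(acts),
        schedule=default_arrival_schedule(SITE_ARRIVAL_SCALES["site2_rural"]),
        tpa_prep_in_imaging_variant=_tri(10.5, 12.5, 14.5),
        baseline_flags=frozenset({"P1", "P3"}))
    return scale_all_durations(cfg, k)


def _site3_config() -> SiteConfig:
    k = SITE_DURATION_SCALES["site3_rural"]
    d = {
        "triage": _tri(2.5, 4.5, 7),
        "registration_pv": _tri(3, 5, 8),
        "recognition": _logn(18.0, 0.95),
        "protocol_activation": _tri(1, 2, 4),
        "ct_callin_delay": _tri(3, 8, 15),
        "ncct": _tri(6, 8.5, 11.5),
        "cta": _tri(4, 6.5, 9.5),
        "labs": _tri(6, 10, 14.5),
        "neuro_assessment": _tri(4, 7, 10),
        "interpretation": _tri(4.5, 6.5, 9),
        # decision by the ED physician: long and variable, comparable to prep
        "decision": _tri(19, 24, 30.5),
        "tpa_prep": _tri(20, 27, 34),
        "travel_imaging_to_ed": _tri(1.5, 2.5, 3.5),
    }
    acts = [
        Activity("pre_notification", "A", _tri(3, 5, 8), applies_to="EMS",
                 role="pre_notification", label="EMS pre-notification received"),
        Activity("transfer_to_ed_bay", "B", _tri(6.2, 7.7, 9.6), applies_to="EMS",
                 role="transfer_to_ed_bay", label="transfer to ED bay"),
        Activity("ems_assessment", "B", _tri(3.5, 5, 7), applies_to="EMS",
                 predecessors=("transfer_to_ed_bay",),
                 label="initial assessment in ED bay"),
        Activity("registration_ems", "B", _tri(0.8, 1.4, 2.2), applies_to="EMS",
                 predecessors=("ems_assessment",), role="registration",
                 label="registration on arrival (EMS)"),
        *_pv_arrival(d),
        Activity("travel_to_imaging", "B", _tri(4, 6, 8),
                 predecessors=("registration_ems", "protocol_activation"),
                 role="travel_to_imaging", label="travel to imaging"),
        *_common_phase_bcd(d),
    ]
    cfg = SiteConfig(
        site_id="site3_rural", activities=tuple(acts),
        schedule=default_arrival_schedule(SITE_ARRIVAL_SCALES["site3_rural"]),
        tpa_prep_in_imaging_variant=_tri(17, 22, 28),
        baseline_flags=frozenset())
    return scale_all_durations(cfg, k)


def default_site_configs() -> dict[str, SiteConfig]:
    """The three shipped site configurations, keyed by site id."""
    configs = {
        "site1_urban": _site1_config(),
        "site2_rural": _site2_config(),
        "site3_rural": _site3_config(),
    }
    for name, cfg in configs.items():
        problems = validate_config(cfg)
        if problems:  # pragma: no cover - shipped fixtures must validate
            raise ConfigError(f"{name}: " + "; ".join(problems))
    return configs


# -- calibration -----------------------------------------------------------------------

def scale_all_durations(config: SiteConfig, k: float) -> SiteConfig:
    """Scale every activity duration (both hours variants) and the prep variant by k."""
    if k <= 0:
        raise ValueError("scale factor must be > 0")
    acts = tuple(
        replace(a,
                duration_regular=a.duration_regular.scaled(k),
                duration_out_of_hours=(None if a.duration_out_of_hours is None
                                       else a.duration_out_of_hours.scaled(k)))
        for a in config.activities)
    return replace(config, activities=acts,
                   tpa_prep_in_imaging_variant=config.tpa_prep_in_imaging_variant.scaled(k))


@dataclass(frozen=True)
class CalibrationResult:
    global_scale: float
    achieved_median: float
    target_median: float
    iterations: int
    converged: bool


def calibrate_global_scale(config: SiteConfig, target_median: float,
                           tolerance: float = 0.5, n_reps: int = 30,
                           horizon_days: int = 365, seed: int = 0,
                           max_iter: int = 40) -> CalibrationResult:
    """Find a global duration multiplier matching the pooled baseline median.

    Runs a stochastic bisection under common random numbers: every trial scale reuses
    the same seeds, making the objective a deterministic, monotone function of the
    scale (with negligible protocol-token contention the pooled median is exactly
    linear in it). The search starts from the proportional guess
    ``target / current_median`` and bisects until the achieved median is within
    ``tolerance`` minutes of the target.
    """
    if target_median <= 0:
        raise ValueError("target_median must be > 0")

    def median_at(k: float) -> float:
        reps = run_experiment(scale_all_durations(config, k), None,
                              n_reps=n_reps, horizon_days=horizon_days,
                              base_seed=seed)
        return pooled_summary(reps).median

    iterations = 0
    m1 = median_at(1.0)
    iterations += 1
    if abs(m1 - target_median) <= tolerance:
        return CalibrationResult(1.0, m1, target_median, iterations, True)

    k = target_median / m1
    lo, hi = 0.8 * k, 1.25 * k
    m_lo, m_hi = median_at(lo), median_at(hi)
    iterations += 2
    expansions = 0
    while m_lo > target_median and expansions < 6:
        lo *= 0.7
        m_lo = median_at(lo)
        iterations += 1
        expansions += 1
    while m_hi < target_median and expansions < 12:
        hi *= 1.4
        m_hi = median_at(hi)
        iterations += 1
        expansions += 1
    if m_lo > target_median or m_hi < target_median:
        raise ValueError("could not bracket the target median")

    best_k, best_m = (lo, m_lo) if abs(m_lo - target_median) < abs(m_hi - target_median) \
        else (hi, m_hi)
    while iterations < max_iter:
        mid = 0.5 * (lo + hi)
        m_mid = median_at(mid)
        iterations += 1
        if abs(m_mid - target_median) < abs(best_m - target_median):
            best_k, best_m = mid, m_mid
        if abs(m_mid - target_median) <= tolerance:
            return CalibrationResult(mid, m_mid, target_median, iterations, True)
        if m_mid < target_median:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(best_k, best_m, target_median, iterations,
                             abs(best_m - target_median) <= tolerance)


# -- supplementary-table transcription -------------------------------------------------

_SM1_COLUMNS = ("site", "role", "hours", "family", "params")


def load_sm1_distributions(path) -> dict[str, SiteConfig]:
    """Apply transcribed duration distributions onto the default configs.

    The transcription schema is CSV with columns ``site, role, hours, family, params``
    and an optional ``variant`` column; ``params`` is slash-separated (e.g.
    ``triangular`` with ``5/10/20``), ``hours`` is ``regular``, ``out`` or ``both``,
    and ``variant=p2_prep`` rows set the site's in-imaging prep distribution.
    Replaced distributions carry ``provenance="SM1"``.
    """
    configs = default_site_configs()
    alias = {"site1": "site1_urban", "site2": "site2_rural", "site3": "site3_rural"}

    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"{path}: transcription file is empty")

    for lineno, row in enumerate(rows, start=2):
        missing = [c for c in _SM1_COLUMNS if not (row.get(c) or "").strip()]
        if missing:
            raise ValueError(f"{path}:{lineno}: missing columns {missing}")
        site = alias.get(row["site"].strip(), row["site"].strip())
        if site not in configs:
            raise ValueError(f"{path}:{lineno}: unknown site {row['site']!r}")
        cfg = configs[site]
        role = row["role"].strip()
        hours = row["hours"].strip()
        if hours not in ("regular", "out", "both"):
            raise ValueError(f"{path}:{lineno}: bad hours class {hours!r}")
        try:
            params = tuple(float(tok) for tok in row["params"].split("/"))
            dist = DurationDistribution(row["family"].strip(), params,
                                        provenance="SM1")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc

        if (row.get("variant") or "").strip() == "p2_prep":
            configs[site] = replace(cfg, tpa_prep_in_imaging_variant=dist)
            continue
        targets = [a for a in cfg.activities if a.role == role]
        if not targets:
            raise ValueError(f"{path}:{lineno}: no activity with role {role!r} "
                             f"at {site}")
        ids = {a.id for a in targets}
        new_acts = []
        for a in cfg.activities:
            if a.id not in ids:
                new_acts.append(a)
            elif hours == "regular":
                new_acts.append(replace(
                    a, duration_regular=dist,
                    duration_out_of_hours=a.duration_out_of_hours
                    or a.duration_regular))
            elif hours == "out":
                new_acts.append(replace(a, duration_out_of_hours=dist))
            else:
                new_acts.append(replace(a, duration_regular=dist,
                                        duration_out_of_hours=None))
        configs[site] = replace(cfg, activities=tuple(new_acts))
    return configs
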