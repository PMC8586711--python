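"""Scenario algebra: pure transformations of a site configuration.

Five improvement scenarios are modelled, matching how the sites describe them:

* **P1** — EMS patients stay on the EMS stretcher to imaging: the transfer-to-ED-bay
  activity is deleted from the EMS graph, its successors inheriting its predecessors.
* **P2** — tPA administered in the imaging area (regular and out of hours): the
  imaging-to-ED travel activity is deleted from every graph and the active tPA-prep
  duration is replaced by the site's in-imaging prep variant (prep in imaging is
  faster because the team is already assembled at the scanner).
* **P3** — pre-registration of EMS patients: the EMS registration activity moves to
  phase A (pre-arrival), contributing zero post-door time but remaining in the record
  for audit completeness.
* **R1** — treatment-decision time reduced by 35% (duration scaled by 0.65).
* **R2** — tPA-preparation time reduced by 35%; when combined with P2 this scales the
  in-imaging variant, i.e. the two reductions compound.

Codes already present in a site's baseline flags are no-ops ("current baseline").
P-codes are applied before R-codes, which makes composition order-independent.
Transformed configs are tagged with the applied codes; re-applying an R-code to an
already-transformed config is an error (it would scale twice), while re-applying a
P-code is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .pathway import Activity, ConfigError, SiteConfig

__all__ = ["ScenarioSpec", "apply_scenarios", "is_baseline_noop",
           "scale_role", "ALL_CODES"]

P_CODES = ("P1", "P2", "P3")
R_CODES = ("R1", "R2")
ALL_CODES = P_CODES + R_CODES


@dataclass(frozen=True)
class ScenarioSpec:
    """A subset of {P1, P2, P3, R1, R2} plus the reduction factor for R-codes."""

    codes: frozenset[str] = frozenset()
    reduction_factor: float = 0.65

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(self.codes))
        unknown = self.codes - set(ALL_CODES)
        if unknown:
            raise ConfigError(f"unknown scenario codes: {sorted(unknown)}")
        if not 0.0 < self.reduction_factor <= 1.0:
            raise ConfigError("reduction_factor must be in (0, 1]")

    @classmethod
    def parse(cls, text: str) -> "ScenarioSpec":
        """Parse strings like ``"P2"``, ``"P1+P2+P3"``, ``"ALL"`` or ``"baseline"``."""
        text = text.strip()
        if text.upper() in ("", "BASELINE", "NONE"):
            return cls(frozenset())
        if text.upper() == "ALL":
            return cls(frozenset(ALL_CODES))
        return cls(frozenset(tok.strip().upper() for tok in text.split("+")))

    def __str__(self) -> str:
        if not self.codes:
            return "baseline"
        return "+".join(sorted(self.codes))


def is_baseline_noop(config: SiteConfig, code: str) -> bool:
    """True iff the site already practices this process change (Table-1 style)."""
    if code not in ALL_CODES:
        raise ConfigError(f"unknown scenario code {code!r}")
    if code in R_CODES:
        return False
    return code in config.baseline_flags


def _delete_role(config: SiteConfig, role: str) -> tuple[SiteConfig, int]:
    """Delete every activity with the given role, rewiring successors."""
    doomed = {a.id: a.predecessors for a in config.activities if a.role == role}
    if not doomed:
        return config, 0

    def rewire(preds: tuple[str, ...]) -> tuple[str, ...]:
        out: list[str] = []
        for p in preds:
            if p in doomed:
                out.extend(q for q in rewire(doomed[p]) if q not in out)
            elif p not in out:
                out.append(p)
        return tuple(out)

    new_acts = tuple(replace(a, predecessors=rewire(a.predecessors))
                     for a in config.activities if a.id not in doomed)
    return replace(config, activities=new_acts), len(doomed)


def apply_scenarios(config: SiteConfig, spec: ScenarioSpec) -> SiteConfig:
    """Return a new config with the scenario transformations applied.

    The input config is untouched. Codes in ``config.baseline_flags`` are skipped.
    """
    reapplied_r = set(spec.codes) & set(R_CODES) & set(config.applied_scenarios)
    if reapplied_r:
        raise ConfigError(
            f"codes {sorted(reapplied_r)} already applied to this config; "
            "re-applying a duration reduction would scale twice")

    cfg = config
    effective = {c for c in spec.codes
                 if not is_baseline_noop(config, c) and c not in config.applied_scenarios}

    # -- process changes first --------------------------------------------------------
    if "P1" in effective:
        cfg, n = _delete_role(cfg, "transfer_to_ed_bay")
        if n == 0:
            raise ConfigError("P1 requires a role=transfer_to_ed_bay activity")
    if "P3" in effective:
        moved = [a for a in cfg.activities
                 if a.role == "registration" and a.applies_to == "EMS"
                 and a.phase != "A"]
        if not moved:
            raise ConfigError("P3 requires a post-door EMS role=registration activity")
        moved_ids = {a.id for a in moved}
        cfg = replace(cfg, activities=tuple(
            replace(a, phase="A") if a.id in moved_ids else a
            for a in cfg.activities))
    if "P2" in effective:
        cfg, n = _delete_role(cfg, "travel_imaging_to_ed")
        if n == 0:
            raise ConfigError("P2 requires a role=travel_imaging_to_ed activity")
        variant = cfg.tpa_prep_in_imaging_variant
        cfg = replace(cfg, activities=tuple(
            replace(a, duration_regular=variant, duration_out_of_hours=None)
            if a.role == "tpa_prep" else a
            for a in cfg.activities))

    # -- duration reductions (scale whatever is active after the P-codes) -------------
    k = spec.reduction_factor
    if "R1" in effective:
        cfg = scale_role(cfg, "decision", k)
    if "R2" in effective:
        cfg = scale_role(cfg, "tpa_prep", k)
        cfg = replace(cfg,
                      tpa_prep_in_imaging_variant=cfg.tpa_prep_in_imaging_variant.scaled(k))

    return replace(cfg, applied_scenarios=config.applied_scenarios | spec.codes)


def scale_role(config: SiteConfig, role: str, factor: float) -> SiteConfig:
    """Scale both hours-variants of every activity carrying ``role`` by ``factor``."""
    if not any(a.role == role for a in config.activities):
        raise ConfigError(f"no activity with role {role!r}")
    new_acts = tuple(
        replace(a,
                duration_regular=a.duration_regular.scaled(factor),
                duration_out_of_hours=(None if a.duration_out_of_hours is None
                                       else a.duration_out_of_hours.scaled(factor)))
        if a.role == role else a
        for a in config.activities)
    return replace(config, activities=new_acts)
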