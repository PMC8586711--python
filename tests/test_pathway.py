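import itertools

import networkx as nx
import numpy as np
import pytest

from dntsim import Activity, critical_path, validate_config
from dntsim.distributions import constant
from dntsim.pathway import ConfigError, effective_predecessors

from conftest import make_config, random_constant_config


def test_shipped_fixture_configs_validate(site_configs):
    for name, cfg in site_configs.items():
        assert validate_config(cfg) == [], name


def test_cycle_violation_names_the_activities():
    cfg = make_config([
        Activity("A", "B", constant(1), predecessors=("B",)),
        Activity("B", "B", constant(1), predecessors=("A",)),
        Activity("decision", "C", constant(1), role="decision"),
        Activity("tpa_prep", "D", constant(1), role="tpa_prep"),
        Activity("bolus", "D", constant(0), predecessors=("decision", "tpa_prep"),
                 role="bolus"),
    ])
    report = validate_config(cfg)
    assert any("cycle" in v and "A" in v and "B" in v for v in report)


def test_missing_bolus_role_reported():
    cfg = make_config([
        Activity("decision", "C", constant(1), role="decision"),
        Activity("tpa_prep", "D", constant(1), role="tpa_prep"),
    ])
    report = validate_config(cfg)
    assert any("role=bolus" in v for v in report)


def test_unknown_predecessor_reported():
    cfg = make_config([
        Activity("decision", "C", constant(1), role="decision",
                 predecessors=("ghost",)),
        Activity("tpa_prep", "D", constant(1), role="tpa_prep"),
        Activity("bolus", "D", constant(0), predecessors=("decision", "tpa_prep"),
                 role="bolus"),
    ])
    assert any("ghost" in v for v in validate_config(cfg))


def test_bad_p_ems_reported(site_configs):
    from dataclasses import replace
    cfg = replace(site_configs["site1_urban"], p_ems=1.5)
    assert any("p_ems" in v for v in validate_config(cfg))


def _serial_chain():
    return make_config([
        Activity("x", "B", constant(5)),
        Activity("y", "C", constant(10), predecessors=("x",)),
        Activity("decision", "C", constant(0), predecessors=("y",),
                 role="decision"),
        Activity("tpa_prep", "D", constant(0), predecessors=("y",),
                 role="tpa_prep"),
        Activity("bolus", "D", constant(0), predecessors=("decision", "tpa_prep"),
                 role="bolus"),
    ])


def test_critical_path_serial_chain():
    cfg = _serial_chain()
    durations = {"x": 5, "y": 10, "decision": 0, "tpa_prep": 0, "bolus": 0}
    length, path = critical_path(cfg, "EMS", "regular", durations)
    assert length == 15.0
    assert path[0] == "x" and path[-1] == "bolus"


def test_critical_path_parallel_branches_takes_maximum():
    """interpretation(10) feeds decision(20) and prep(30); bolus needs both."""
    cfg = make_config([
        Activity("interpretation", "C", constant(10), role="interpretation"),
        Activity("decision", "C", constant(20), predecessors=("interpretation",),
                 role="decision"),
        Activity("tpa_prep", "D", constant(30), predecessors=("interpretation",),
                 role="tpa_prep"),
        Activity("bolus", "D", constant(0), predecessors=("decision", "tpa_prep"),
                 role="bolus"),
    ])
    durations = {"interpretation": 10, "decision": 20, "tpa_prep": 30, "bolus": 0}
    length, path = critical_path(cfg, "PV", "out_of_hours", durations)
    assert length == 40.0
    assert path == ["interpretation", "tpa_prep", "bolus"]


def test_critical_path_all_zero_durations():
    cfg = _serial_chain()
    length, path = critical_path(cfg, "EMS", "regular",
                                 dict.fromkeys(["x", "y", "decision",
                                                "tpa_prep", "bolus"], 0.0))
    assert length == 0.0
    assert path[-1] == "bolus"


def test_critical_path_missing_duration_raises():
    cfg = _serial_chain()
    with pytest.raises(ConfigError, match="missing fixed durations"):
        critical_path(cfg, "EMS", "regular", {"x": 5})


def _brute_force_longest(cfg, pathway, hours, durations):
    """Independent oracle: enumerate every source-to-bolus path with networkx."""
    preds = effective_predecessors(cfg, pathway, hours)
    g = nx.DiGraph()
    g.add_nodes_from(preds)
    for aid, ps in preds.items():
        g.add_edges_from((p, aid) for p in ps)
    bolus = next(a.id for a in cfg.activities if a.role == "bolus")
    sources = [n for n in g if g.in_degree(n) == 0]
    best = 0.0
    for s in sources:
        for path in nx.all_simple_paths(g, s, bolus):
            best = max(best, sum(durations[a] for a in path if a != bolus))
        if s == bolus:
            best = max(best, 0.0)
    return best


def test_critical_path_equals_brute_force_enumeration():
    rng = np.random.default_rng(21)
    for _ in range(30):
        cfg = random_constant_config(rng)
        durations = {a.id: a.duration_regular.params[0] for a in cfg.activities}
        length, _ = critical_path(cfg, "EMS", "regular", durations)
        assert length == _brute_force_longest(cfg, "EMS", "regular", durations)


def test_critical_path_invariant_to_activity_order():
    rng = np.random.default_rng(5)
    cfg = random_constant_config(rng)
    durations = {a.id: a.duration_regular.params[0] for a in cfg.activities}
    ref = critical_path(cfg, "EMS", "regular", durations)[0]
    for perm in itertools.islice(itertools.permutations(cfg.activities), 8):
        from dataclasses import replace
        shuffled = replace(cfg, activities=tuple(perm))
        assert critical_path(shuffled, "EMS", "regular", durations)[0] == ref


def test_parallel_activity_below_critical_length_changes_nothing():
    cfg = _serial_chain()
    durations = {"x": 5, "y": 10, "decision": 0, "tpa_prep": 0, "bolus": 0}
    base_len = critical_path(cfg, "EMS", "regular", durations)[0]
    extra = Activity("side", "B", constant(base_len - 1))
    from dataclasses import replace
    widened = replace(cfg, activities=cfg.activities[:-1] + (
        extra,
        replace(cfg.activity("bolus"),
                predecessors=("decision", "tpa_prep", "side"))))
    durations["side"] = base_len - 1
    assert critical_path(widened, "EMS", "regular", durations)[0] == base_len


def test_pathway_projection_bypasses_inapplicable_activities(site_configs):
    """EMS graphs skip the walk-in arrival chain; PV graphs skip EMS-only work."""
    cfg = site_configs["site3_rural"]
    ems = effective_predecessors(cfg, "EMS", "regular")
    pv = effective_predecessors(cfg, "PV", "regular")
    assert "triage" not in ems and "transfer_to_ed_bay" in ems
    assert "transfer_to_ed_bay" not in pv and "triage" in pv
    # travel_to_imaging inherits through the bypassed branch in each projection
    assert ems["travel_to_imaging"] == {"registration_ems"}
    assert pv["travel_to_imaging"] == {"protocol_activation"}


def test_hours_projection_controls_rural_callin_delay(site_configs):
    cfg = site_configs["site2_rural"]
    assert "ct_callin_delay" not in effective_predecessors(cfg, "EMS", "regular")
    out = effective_predecessors(cfg, "EMS", "out_of_hours")
    assert out["ncct"] == {"ct_callin_delay", "travel_to_imaging"}
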