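import numpy as np
import pytest

from dntsim import Activity, ArrivalSchedule, SiteConfig
from dntsim.distributions import constant, triangular
from dntsim.fixtures import TABLE_BLOCK_RATES, default_site_configs


@pytest.fixture(scope="session")
def site_configs():
    return default_site_configs()


@pytest.fixture(scope="session")
def table_schedule():
    return ArrivalSchedule(TABLE_BLOCK_RATES)


def make_config(activities, p_ems=0.8, scale=1.0, flags=(),
                variant=None) -> SiteConfig:
    """Minimal config around an explicit activity list (low arrival rate)."""
    return SiteConfig(
        site_id="toy",
        activities=tuple(activities),
        schedule=ArrivalSchedule((0.001,) * 12, scale=scale),
        tpa_prep_in_imaging_variant=variant or triangular(2, 3, 4),
        p_ems=p_ems,
        baseline_flags=frozenset(flags))


def chain_config(durations, p_ems=0.8) -> SiteConfig:
    """Serial chain ...->decision->tpa_prep->bolus with constant durations.

    ``durations`` maps ids to minutes for extra chain links inserted before the
    decision; decision and tpa_prep default to 0 unless present in the map.
    """
    acts = []
    prev = ()
    for name, minutes in durations.items():
        if name in ("decision", "tpa_prep", "bolus"):
            continue
        acts.append(Activity(name, "B", constant(minutes), predecessors=prev))
        prev = (name,)
    acts.append(Activity("decision", "C", constant(durations.get("decision", 0.0)),
                         predecessors=prev, role="decision"))
    acts.append(Activity("tpa_prep", "D", constant(durations.get("tpa_prep", 0.0)),
                         predecessors=prev, role="tpa_prep"))
    acts.append(Activity("bolus", "D", constant(durations.get("bolus", 0.0)),
                         predecessors=("decision", "tpa_prep"), role="bolus"))
    return make_config(acts)


def random_constant_config(rng: np.random.Generator) -> SiteConfig:
    """A random constant-duration DAG config with the three mandatory roles.

    Between 0 and 7 extra activities are wired with random predecessors among the
    earlier nodes, then interpretation -> (decision, tpa_prep) -> bolus closes the
    graph, so every config validates while exercising varied shapes.
    """
    n_extra = int(rng.integers(0, 8))
    acts = []
    ids = []
    for i in range(n_extra):
        preds = tuple(x for x in ids if rng.random() < 0.4)
        acts.append(Activity(f"a{i}", "B", constant(float(rng.integers(0, 20))),
                             predecessors=preds))
        ids.append(f"a{i}")
    acts.append(Activity("interpretation", "C",
                         constant(float(rng.integers(0, 15))),
                         predecessors=tuple(ids), role="interpretation"))
    acts.append(Activity("decision", "C", constant(float(rng.integers(0, 25))),
                         predecessors=("interpretation",), role="decision"))
    acts.append(Activity("tpa_prep", "D", constant(float(rng.integers(0, 25))),
                         predecessors=("interpretation",), role="tpa_prep"))
    acts.append(Activity("bolus", "D", constant(1.0),
                         predecessors=("decision", "tpa_prep"), role="bolus"))
    return make_config(acts)


@pytest.fixture
def config_factory():
    return make_config


@pytest.fixture
def random_config_factory():
    return random_constant_config
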