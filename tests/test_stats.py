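import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from dntsim import (chi_square_gof, mann_whitney_u, percent_reduction_ci,
                    pooled_summary, replications_needed, sensitivity_sweep)
from dntsim.stats import summary_from_dnts

# Printed verification table: observed simulated block volumes vs desired volumes.
OBSERVED_VOLUMES = [79, 78, 77, 146, 342, 375, 415, 349, 376, 358, 218, 208]
DESIRED_VOLUMES = [93.7, 70.4, 70.4, 140.5, 304.5, 398.2, 421.4, 374.6, 374.6,
                   351.3, 234.1, 187.3]


def test_pooled_median_simple():
    s = summary_from_dnts(np.array([1, 2, 3, 4, 5.0]))
    assert s.median == 3.0 and s.n == 5


def test_p90_of_two_point_mass():
    x = np.array([1.0] * 10 + [2.0] * 90)
    assert summary_from_dnts(x).p90 == 2.0


def test_pooling_concatenates_rather_than_averaging_medians():
    """Unequal replication sizes: pooled quantile != mean of per-rep medians."""
    reps = [np.array([10.0]), np.array([20.0] * 99)]
    s = pooled_summary(reps)
    assert s.median == 20.0
    assert s.median != np.mean([np.median(r) for r in reps])
    assert s.n == 100


def test_summary_orderings(site_configs):
    from dntsim import run_experiment
    reps = run_experiment(site_configs["site2_rural"], None, n_reps=2,
                          horizon_days=120, base_seed=0)
    s = pooled_summary(reps)
    assert s.q25 <= s.median <= s.q75
    assert s.p90 >= s.median


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        summary_from_dnts(np.array([]))
    with pytest.raises(ValueError):
        pooled_summary([np.array([])])


def test_identical_arms_give_zero_reduction():
    rng = np.random.default_rng(0)
    reps = [50 + rng.standard_normal(40) for _ in range(10)]
    res = percent_reduction_ci(reps, reps, n_boot=200,
                               rng=np.random.default_rng(1))
    assert res.median_reduction_pct == 0.0
    assert res.median_ci95[0] <= 0.0 <= res.median_ci95[1]
    assert res.mwu_p > 0.9


def test_exact_halving_gives_fifty_percent_degenerate_ci():
    rng = np.random.default_rng(2)
    base = [50 + rng.standard_normal(40) for _ in range(8)]
    scen = [0.5 * r for r in base]
    res = percent_reduction_ci(base, scen, n_boot=200,
                               rng=np.random.default_rng(3))
    assert res.median_reduction_pct == pytest.approx(50.0)
    assert res.median_ci95 == pytest.approx((50.0, 50.0), abs=1.5)


def test_reduction_needs_two_replications():
    with pytest.raises(ValueError):
        percent_reduction_ci([np.ones(5)], [np.ones(5), np.ones(5)])


def test_mwu_identical_samples_p_near_one():
    x = np.arange(30.0)
    _, p = mann_whitney_u(x, x.copy())
    assert p > 0.95


def test_mwu_exact_small_sample_matches_enumeration():
    """x={1,2}, y={3,4}: enumerate all C(4,2)=6 rank splits -> p = 2/6."""
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    pooled = [1, 2, 3, 4]
    count = 0
    total = 0
    for xs in itertools.combinations(range(4), 2):
        ys = [i for i in range(4) if i not in xs]
        u_perm = sum(1 for i in xs for j in ys if pooled[i] > pooled[j])
        total += 1
        count += min(u_perm, 4 - u_perm) <= 0  # as extreme as observed U=0
    assert p == pytest.approx(count / total)  # = 2/6


def test_mwu_rejects_empty():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1, 2])


def test_chi_square_exact_fit():
    stat, p = chi_square_gof([5, 5, 5], [5, 5, 5])
    assert stat == 0.0 and p == 1.0


def test_chi_square_on_published_verification_volumes():
    stat, p = chi_square_gof(OBSERVED_VOLUMES, DESIRED_VOLUMES)
    assert p == pytest.approx(0.169, abs=0.002)


def test_chi_square_closed_form_tail():
    stat, p = chi_square_gof([10, 0], [5, 5])
    assert stat == 10.0
    assert p == pytest.approx(float(sps.chi2.sf(10, 1)), rel=1e-9)
    assert p == pytest.approx(0.00157, abs=2e-5)


def test_chi_square_invariant_under_permutation():
    rng = np.random.default_rng(4)
    o = rng.integers(10, 50, size=8).astype(float)
    e = rng.uniform(10, 50, size=8)
    perm = rng.permutation(8)
    assert chi_square_gof(o, e)[0] == pytest.approx(
        chi_square_gof(o[perm], e[perm])[0])


def test_chi_square_input_validation():
    with pytest.raises(ValueError):
        chi_square_gof([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        chi_square_gof([1, 2], [1, 0])


def test_replications_needed():
    assert replications_needed([50.0, 50.0, 50.0]) == 2
    # pilot mean 50, sd 5, 5% precision, 95% confidence -> t-iteration gives 18
    pilot = [45.0, 50.0, 55.0]
    sd = np.std(pilot, ddof=1)
    scaled = 50 + (np.array(pilot) - 50) * 5 / sd
    assert replications_needed(scaled, 0.05, 0.95) == 18
    assert (replications_needed(scaled, 0.025, 0.95)
            >= replications_needed(scaled, 0.05, 0.95))
    with pytest.raises(ValueError):
        replications_needed([-1.0, 1.0])


def test_bootstrap_ci_covers_known_median_reduction():
    """95% CIs cover a known 20% reduction in >=90% of 200 seeded trials."""
    rng = np.random.default_rng(42)
    covered = 0
    trials = 200
    for _ in range(trials):
        base = [50 * np.exp(0.3 * rng.standard_normal(60)) for _ in range(30)]
        scen = [40 * np.exp(0.3 * rng.standard_normal(60)) for _ in range(30)]
        res = percent_reduction_ci(base, scen, n_boot=250, rng=rng)
        lo, hi = res.median_ci95
        covered += lo <= 20.0 <= hi
    assert covered >= 0.90 * trials


def test_sensitivity_sweep_consistency(site_configs):
    from dntsim import ScenarioSpec, run_experiment
    cfg = site_configs["site3_rural"]
    sweep = sensitivity_sweep(cfg, [("decision", 1.0), ("decision", 0.65)],
                              n_reps=2, horizon_days=120, base_seed=9)
    unperturbed = pooled_summary(run_experiment(cfg, None, n_reps=2,
                                                horizon_days=120, base_seed=9))
    assert sweep[0][2] == unperturbed  # factor 1.0 reproduces baseline exactly
    r1 = pooled_summary(run_experiment(cfg, ScenarioSpec.parse("R1"), n_reps=2,
                                       horizon_days=120, base_seed=9))
    assert sweep[1][2] == r1  # scaling decision by 0.65 is exactly R1
    assert sweep[1][2].median <= sweep[0][2].median  # monotone under CRN
    with pytest.raises(ValueError, match="unknown role"):
        sensitivity_sweep(cfg, [("no_such_role", 0.9)], n_reps=1,
                          horizon_days=30)
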