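"""Outcome measures and statistical machinery.

The primary outcome is the median door-to-needle time (DNT) pooled over all
replications, with the interquartile range as the spread measure and the 90th
percentile as the guideline benchmark (Canadian guidelines target a 90th-percentile
DNT of 60 minutes). Quantiles use numpy's linear-interpolation definition throughout.

Baseline-vs-scenario comparisons report percentage reductions,
``100 * (baseline - scenario) / baseline``, for the median, the IQR width and the 90th
percentile. Confidence intervals are percentile-bootstrap over replications: each
bootstrap draw resamples whole replications with replacement within each arm,
recomputes the pooled metrics and the reduction. The Mann-Whitney U test compares
pooled DNT samples; the chi-square goodness-of-fit test verifies arrival counts
against the desired schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "ComparisonResult",
    "pooled_summary",
    "summary_from_dnts",
    "percent_reduction_ci",
    "mann_whitney_u",
    "chi_square_gof",
    "replications_needed",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class SummaryStats:
    """Pooled DNT summary: count, median, IQR endpoints and 90th percentile."""

    n: int
    median: float
    q25: float
    q75: float
    p90: float

    @property
    def iqr_width(self) -> float:
        return self.q75 - self.q25


@dataclass(frozen=True)
class ComparisonResult:
    """Baseline-vs-scenario reductions (in %), bootstrap CIs and the MWU p-value."""

    median_reduction_pct: float
    iqr_reduction_pct: float
    p90_reduction_pct: float
    median_ci95: tuple[float, float]
    iqr_ci95: tuple[float, float]
    p90_ci95: tuple[float, float]
    mwu_p: float


def summary_from_dnts(dnts: np.ndarray) -> SummaryStats:
    dnts = np.asarray(dnts, dtype=float)
    if dnts.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q25, med, q75, p90 = np.quantile(dnts, [0.25, 0.5, 0.75, 0.90])
    return SummaryStats(n=int(dnts.size), median=float(med),
                        q25=float(q25), q75=float(q75), p90=float(p90))


def pooled_summary(replications) -> SummaryStats:
    """Summary of the concatenated DNT sample across replications.

    Accepts either a list of per-replication :class:`~dntsim.engine.PatientRecord`
    lists or a list of per-replication DNT arrays. Pooling concatenates first: the
    result is the quantile of the pooled sample, not a mean of per-replication
    quantiles (replications with more patients weigh more, as they should).
    """
    arrays = [_as_dnts(rep) for rep in replications]
    if not arrays or all(a.size == 0 for a in arrays):
        raise ValueError("cannot summarize empty replications")
    return summary_from_dnts(np.concatenate(arrays))


def _as_dnts(rep) -> np.ndarray:
    if isinstance(rep, np.ndarray):
        return rep.astype(float)
    if len(rep) and hasattr(rep[0], "dnt"):
        return np.array([r.dnt for r in rep])
    return np.asarray(rep, dtype=float)


def _reductions(base: SummaryStats, scen: SummaryStats,
                strict: bool = True) -> tuple[float, float, float]:
    if strict and (base.median == 0 or base.iqr_width == 0 or base.p90 == 0):
        raise ValueError("baseline metric is zero; reduction undefined")

    def pct(b, s):
        return 100.0 * (b - s) / b if b else float("nan")

    return (pct(base.median, scen.median), pct(base.iqr_width, scen.iqr_width),
            pct(base.p90, scen.p90))


def percent_reduction_ci(baseline, scenario, n_boot: int = 10_000,
                         rng: np.random.Generator | None = None) -> ComparisonResult:
    """Point reductions from pooled summaries with percentile-bootstrap 95% CIs.

    ``baseline`` and ``scenario`` are per-replication collections (records or DNT
    arrays). Bootstrap resamples replications with replacement within each arm.
    """
    base_arrays = [_as_dnts(rep) for rep in baseline]
    scen_arrays = [_as_dnts(rep) for rep in scenario]
    if len(base_arrays) < 2 or len(scen_arrays) < 2:
        raise ValueError("need at least 2 replications per arm for a bootstrap CI")
    rng = rng if rng is not None else np.random.default_rng()

    base_stat = summary_from_dnts(np.concatenate(base_arrays))
    scen_stat = summary_from_dnts(np.concatenate(scen_arrays))
    point = _reductions(base_stat, scen_stat)

    nb, ns = len(base_arrays), len(scen_arrays)
    draws = np.empty((n_boot, 3))
    for b in range(n_boot):
        # resampling whole replications can draw only empty ones at tiny
        # volumes; redraw in that case so every bootstrap sample is summarizable
        for _ in range(1000):
            bi = rng.integers(0, nb, size=nb)
            si = rng.integers(0, ns, size=ns)
            bx = np.concatenate([base_arrays[i] for i in bi])
            sx = np.concatenate([scen_arrays[i] for i in si])
            if bx.size and sx.size:
                break
        else:
            raise ValueError("bootstrap cannot find non-empty replications")
        draws[b] = _reductions(summary_from_dnts(bx), summary_from_dnts(sx),
                               strict=False)
    lo = np.nanpercentile(draws, 2.5, axis=0)
    hi = np.nanpercentile(draws, 97.5, axis=0)

    _, p = mann_whitney_u(np.concatenate(base_arrays), np.concatenate(scen_arrays))
    return ComparisonResult(
        median_reduction_pct=point[0], iqr_reduction_pct=point[1],
        p90_reduction_pct=point[2],
        median_ci95=(float(lo[0]), float(hi[0])),
        iqr_ci95=(float(lo[1]), float(hi[1])),
        p90_ci95=(float(lo[2]), float(hi[2])),
        mwu_p=float(p))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both samples have n <= 8 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_square_gof(observed, expected) -> tuple[float, float]:
    """Pearson goodness-of-fit: sum (O-E)^2/E against chi-square with k-1 df."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.size < 2:
        raise ValueError("observed and expected must have equal length >= 2")
    if np.any(expected <= 0):
        raise ValueError("expected counts must all be > 0")
    stat = float(np.sum((observed - expected) ** 2 / expected))
    p = float(sps.chi2.sf(stat, df=observed.size - 1))
    return stat, p


def replications_needed(pilot_values, relative_precision: float = 0.05,
                        confidence: float = 0.95, n_max: int = 10_000) -> int:
    """Smallest n whose t-based CI half-width meets the target relative precision.

    Standard sequential replication-count analysis for simulation output: using the
    pilot mean and standard deviation, find the smallest n >= 2 with
    ``t(1-(1-confidence)/2, n-1) * s / sqrt(n) <= relative_precision * mean``.
    """
    vals = np.asarray(pilot_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 pilot values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("pilot mean is zero; relative precision undefined")
    sd = vals.std(ddof=1)
    target = relative_precision * abs(mean)
    if sd == 0:
        return 2
    for n in range(2, n_max + 1):
        half = sps.t.ppf(1 - (1 - confidence) / 2, n - 1) * sd / np.sqrt(n)
        if half <= target:
            return n
    raise ValueError(f"no n <= {n_max} achieves the requested precision")


def sensitivity_sweep(config, grid, scenario=None, n_reps: int = 10,
                      horizon_days: int = 365, base_seed: int = 0):
    """One-at-a-time sensitivity analysis over (activity role, scale factor) pairs.

    For each grid point the named role's duration distributions are scaled by the
    factor, the experiment re-run under common random numbers, and the pooled summary
    recorded. Returns a list of ``(role, factor, SummaryStats)``.
    """
    from .engine import run_experiment
    from .scenarios import scale_role

    out = []
    for role, factor in grid:
        if not any(a.role == role for a in config.activities):
            raise ValueError(f"unknown role {role!r}")
        cfg = scale_role(config, role, factor) if factor != 1.0 else config
        reps = run_experiment(cfg, scenario, n_reps=n_reps,
                              horizon_days=horizon_days, base_seed=base_seed)
        out.append((role, factor, pooled_summary(reps)))
    return out
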