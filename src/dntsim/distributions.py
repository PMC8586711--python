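"""Parametric activity-duration distributions.

Every activity time in the pathway model is drawn from a :class:`DurationDistribution`,
a small immutable value object supporting reproducible sampling, deterministic scaling
(used by the 35%-reduction scenarios) and closed-form quantiles (used by calibration
and by tests).

All times are real-valued minutes. Sampling is implemented as an inverse-CDF transform
of a single uniform draw per sample, which gives two guarantees the simulation relies
on:

* **seed determinism** — equal (distribution, seed) pairs yield identical streams;
* **exact scale equivariance** — ``scale(d, k)`` sampled with the same stream yields
  exactly ``k`` times the original samples, so common-random-number comparisons between
  a baseline and a duration-reduction scenario are noise-free.

The truncated-normal family enforces its lower bound by inverse-CDF truncation
(conditioning the law on ``[lower_bound, inf)``), which is identical in distribution to
resampling out-of-range draws but keeps the one-uniform-per-sample stream layout and is
exactly scale-equivariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "DurationDistribution",
    "FAMILIES",
    "constant",
    "uniform",
    "triangular",
    "exponential",
    "lognormal",
    "truncated_normal",
    "empirical",
    "sample_duration",
    "scale_distribution",
    "distribution_median",
    "distribution_quantile",
]

FAMILIES = (
    "constant",
    "uniform",
    "triangular",
    "exponential",
    "lognormal",
    "truncated_normal",
    "empirical",
)


class DistributionError(ValueError):
    """Invalid family or parameters."""


@dataclass(frozen=True)
class DurationDistribution:
    """A duration law in minutes.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    params
        Family-specific parameters, all in minutes unless noted:

        ``constant``:          ``(value,)``
        ``uniform``:           ``(low, high)`` with ``low <= high``
        ``triangular``:        ``(low, mode, high)`` with ``low <= mode <= high``
        ``exponential``:       ``(mean,)`` with ``mean > 0``
        ``lognormal``:         ``(median, sigma)`` — sigma is the log-scale sd
        ``truncated_normal``:  ``(mu, sd)`` — truncated below at ``lower_bound``
        ``empirical``:         atoms, non-empty, each ``>= lower_bound``
    lower_bound
        Minimum attainable value. Bounded families must start at or above it;
        exponential and lognormal are shifted so their support starts exactly at it.
    provenance
        Free tag recording where the parameters came from (``"SM1"`` for transcribed
        supplementary values, ``"calibrated"`` for shipped stand-ins).
    """

    family: str
    params: tuple[float, ...]
    lower_bound: float = 0.0
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DistributionError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p, lb = self.params, self.lower_bound
        if lb < 0:
            raise DistributionError("lower_bound must be >= 0")
        n_expected = {"constant": 1, "uniform": 2, "triangular": 3,
                      "exponential": 1, "lognormal": 2, "truncated_normal": 2}
        if self.family != "empirical" and len(p) != n_expected[self.family]:
            raise DistributionError(
                f"{self.family} takes {n_expected[self.family]} parameters, got {len(p)}")
        if self.family == "constant" and p[0] < lb:
            raise DistributionError("constant value below lower_bound")
        if self.family == "uniform" and not (lb <= p[0] <= p[1]):
            raise DistributionError("uniform requires lower_bound <= low <= high")
        if self.family == "triangular" and not (lb <= p[0] <= p[1] <= p[2]):
            raise DistributionError(
                "triangular requires lower_bound <= low <= mode <= high")
        if self.family == "exponential" and p[0] <= 0:
            raise DistributionError("exponential mean must be > 0")
        if self.family == "lognormal" and (p[0] <= 0 or p[1] <= 0):
            raise DistributionError("lognormal requires median > 0 and sigma > 0")
        if self.family == "truncated_normal" and p[1] <= 0:
            raise DistributionError("truncated_normal sd must be > 0")
        if self.family == "empirical":
            if not p:
                raise DistributionError("empirical requires at least one atom")
            if min(p) < lb:
                raise DistributionError("empirical atom below lower_bound")
            object.__setattr__(self, "params", tuple(sorted(p)))

    # -- closed-form quantile function ------------------------------------------------

    def ppf(self, q: float) -> float:
        """Inverse CDF at ``q`` in [0, 1)."""
        p, lb = self.params, self.lower_bound
        f = self.family
        if f == "constant":
            return p[0]
        if f == "uniform":
            return p[0] + q * (p[1] - p[0])
        if f == "triangular":
            a, m, b = p
            if b == a:
                return a
            fc = (m - a) / (b - a)
            if q < fc:
                return a + math.sqrt(q * (b - a) * (m - a))
            return b - math.sqrt((1.0 - q) * (b - a) * (b - m))
        if f == "exponential":
            return lb - (p[0] - lb) * math.log1p(-q) if p[0] > lb else lb
        if f == "lognormal":
            # params give the median of the unshifted law; support starts at lb
            return lb + (p[0] - lb) * math.exp(p[1] * ndtri(q)) if p[0] > lb else lb
        if f == "truncated_normal":
            mu, sd = p
            lo = ndtr((lb - mu) / sd)
            return mu + sd * float(ndtri(lo + q * (1.0 - lo)))
        # empirical: atoms are sorted
        idx = min(int(q * len(p)), len(p) - 1)
        return p[idx]

    def sample(self, rng: np.random.Generator) -> float:
        """One draw, consuming exactly one uniform from ``rng``."""
        return self.ppf(rng.random())

    def sample_n(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        return np.array([self.ppf(v) for v in u])

    def scaled(self, factor: float) -> "DurationDistribution":
        """Multiply the law by ``factor`` (> 0); see :func:`scale_distribution`."""
        if factor <= 0:
            raise DistributionError("scale factor must be > 0")
        if factor == 1.0:
            return self
        f = self.family
        if f == "lognormal":
            new = (self.params[0] * factor, self.params[1])
        elif f == "exponential":
            new = (self.params[0] * factor,)
        else:
            new = tuple(p * factor for p in self.params)
        return replace(self, params=new, lower_bound=self.lower_bound * factor)

    def median(self) -> float:
        if self.family == "empirical":
            return float(np.median(self.params))
        return self.ppf(0.5)

    def mean(self) -> float:
        """Closed-form mean where one exists (used by tests and reporting)."""
        p, lb, f = self.params, self.lower_bound, self.family
        if f == "constant":
            return p[0]
        if f == "uniform":
            return 0.5 * (p[0] + p[1])
        if f == "triangular":
            return (p[0] + p[1] + p[2]) / 3.0
        if f == "exponential":
            return p[0]
        if f == "lognormal":
            return lb + (p[0] - lb) * math.exp(0.5 * p[1] ** 2)
        if f == "empirical":
            return float(np.mean(p))
        # truncated normal
        mu, sd = p
        a = (lb - mu) / sd
        return mu + sd * math.exp(-0.5 * a * a) / math.sqrt(2 * math.pi) / (1.0 - ndtr(a))


# -- convenience constructors ----------------------------------------------------------

def constant(value: float, **kw) -> DurationDistribution:
    return DurationDistribution("constant", (value,), **kw)


def uniform(low: float, high: float, **kw) -> DurationDistribution:
    return DurationDistribution("uniform", (low, high), **kw)


def triangular(low: float, mode: float, high: float, **kw) -> DurationDistribution:
    return DurationDistribution("triangular", (low, mode, high), **kw)


def exponential(mean: float, **kw) -> DurationDistribution:
    return DurationDistribution("exponential", (mean,), **kw)


def lognormal(median: float, sigma: float, **kw) -> DurationDistribution:
    return DurationDistribution("lognormal", (median, sigma), **kw)


def truncated_normal(mu: float, sd: float, **kw) -> DurationDistribution:
    return DurationDistribution("truncated_normal", (mu, sd), **kw)


def empirical(atoms, **kw) -> DurationDistribution:
    return DurationDistribution("empirical", tuple(atoms), **kw)


# -- functional aliases matching the module's operation surface ------------------------

def sample_duration(dist: DurationDistribution, rng: np.random.Generator) -> float:
    return dist.sample(rng)


def scale_distribution(dist: DurationDistribution, factor: float) -> DurationDistribution:
    return dist.scaled(factor)


def distribution_median(dist: DurationDistribution) -> float:
    return dist.median()


def distribution_quantile(dist: DurationDistribution, q: float) -> float:
    return dist.ppf(q)
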