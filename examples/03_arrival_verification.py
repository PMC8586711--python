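"""Verify the non-homogeneous Poisson arrival process against its design targets.

Arrivals follow twelve two-hour block rates, identical across days of week. Pooling
30 one-year replications, the observed block counts are compared to the desired
volumes with a chi-square goodness-of-fit test, and the regular-hours share
(Mon-Fri 08:00-16:00) to its analytic value.
"""

import numpy as np

from dntsim import (chi_square_gof, classify_hours, expected_regular_fraction,
                    generate_arrivals)
from dntsim.fixtures import TABLE_BLOCK_RATES, default_arrival_schedule

schedule = default_arrival_schedule()
rng = np.random.default_rng(1)
observed = np.zeros(12)
n_regular = total = 0
for _ in range(30):
    t = generate_arrivals(schedule, 365, rng)
    observed += np.bincount(((t % 1440) // 120).astype(int), minlength=12)
    n_regular += sum(classify_hours(x) == "regular" for x in t)
    total += t.size

expected = np.array(TABLE_BLOCK_RATES) * 2 * 365 * 30
print(f"{'block':>13s} {'expected':>9s} {'observed':>9s}")
for i in range(12):
    print(f"{2*i:02d}:00-{2*i+2:02d}:00 {expected[i]:9.1f} {observed[i]:9.0f}")

stat, p = chi_square_gof(observed, expected)
print(f"\ntotal arrivals over 30 years: {total} (expected "
      f"{expected.sum():.0f})")
print(f"chi-square GOF: statistic {stat:.2f}, p = {p:.3f} "
      "(> 0.05: counts consistent with the schedule)")
print(f"regular-hours share: simulated {100 * n_regular / total:.1f}%, "
      f"analytic {100 * expected_regular_fraction(schedule):.1f}%")
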