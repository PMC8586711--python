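"""Compare improvement scenarios at the rural site that practices none of them.

Each scenario transforms the site configuration (removing work or shortening a
duration) and is re-simulated under common random numbers, so differences are pure
treatment effects. Reductions are percentage drops of the pooled median DNT with
percentile-bootstrap 95% confidence intervals over replications.
"""

import numpy as np

from dntsim import (ScenarioSpec, percent_reduction_ci, pooled_summary,
                    run_experiment)
from dntsim.fixtures import default_site_configs

config = default_site_configs()["site3_rural"]
baseline = run_experiment(config, None, n_reps=30, base_seed=7)
b = pooled_summary(baseline)
print(f"{config.site_id} baseline: median {b.median:.1f} "
      f"(IQR {b.q25:.1f}-{b.q75:.1f}) min, p90 {b.p90:.1f} min\n")

print(f"{'scenario':16s} {'median':>7s} {'reduction':>10s} {'95% CI':>14s}")
for label in ("P1", "P2", "P3", "R1", "R2", "R1+R2", "P1+P2+P3", "ALL"):
    spec = ScenarioSpec.parse(label)
    scen = run_experiment(config, spec, n_reps=30, base_seed=7)
    s = pooled_summary(scen)
    res = percent_reduction_ci(baseline, scen, n_boot=2000,
                               rng=np.random.default_rng(0))
    lo, hi = res.median_ci95
    print(f"{str(spec):16s} {s.median:7.1f} {res.median_reduction_pct:9.1f}% "
          f"({lo:5.1f}-{hi:5.1f}%)")

print("\nKeeping EMS patients on the stretcher (P1) is the strongest single "
      "change here; the decision (R1) and prep (R2) reductions do little alone "
      "but combine super-additively because the two branches run in parallel "
      "and the bottleneck merely moves when only one of them shrinks.")
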