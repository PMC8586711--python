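"""Calibrate a site's global duration scale to a target baseline median.

Every activity duration is multiplied by one global factor; under common random
numbers the pooled median is a monotone (essentially linear) function of it, so a
stochastic bisection pins the baseline to any observed median. This is how the
shipped stand-in configurations were matched to their sites' observed medians.
"""

from dntsim import calibrate_global_scale, scale_all_durations
from dntsim.fixtures import default_site_configs

config = default_site_configs()["site2_rural"]
slowed = scale_all_durations(config, 1.2)  # pretend the site is 20% slower

result = calibrate_global_scale(slowed, target_median=40.1, tolerance=0.3,
                                n_reps=10, seed=3)
print(f"target median    : {result.target_median:.1f} min")
print(f"recovered scale  : {result.global_scale:.4f} (truth: 1/1.2 = 0.8333)")
print(f"achieved median  : {result.achieved_median:.2f} min "
      f"after {result.iterations} simulation runs "
      f"(converged: {result.converged})")
print("\nThe bisection recovers the inflation almost exactly because a uniform "
      "duration scale moves every patient's DNT proportionally.")
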