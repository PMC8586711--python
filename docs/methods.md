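# Methods

## Model

Each treated stroke patient is an independent episode over a directed acyclic
activity graph with four phases: **A** pre-arrival (hospital work triggered by EMS
pre-notification), **B** arrival, **C** imaging and treatment decision, **D**
treatment. Execution is earliest-start: an activity begins at the latest finish of
its predecessors, the first post-door activity additionally waits for the door time
and for the stroke-protocol token, and the door-to-needle time (DNT) is the start
of the bolus activity. With fixed durations this equals the longest door→bolus path
(`pathway.critical_path` is the deterministic oracle the event engine is tested
against), which is why only reductions on the critical path shorten the DNT.

Model assumptions, stated explicitly:

1. stroke patients have top resource priority; staff and equipment are always
   available (the only contended resource is the protocol token);
2. pathway assignments (EMS vs private vehicle, Bernoulli with p = 0.80) are
   independent across patients;
3. EMS always delivers pre-notification, so phase-A work costs no post-door time;
4. activity durations are mutually independent;
5. every simulated patient is eligible for and receives thrombolysis (so treated
   counts equal arrival counts);
6. at most one protocol activation at a time — a capacity-one token, FIFO by door
   time, held from the first post-door activity until the bolus start;
7. full protocol compliance; the possibility that the decision does not wait for
   labs is absorbed into the labs duration law rather than modelled as a branch.

Simplifications: durations do not depend on symptom-onset time; stroke mimics,
hemorrhagic strokes, ineligible patients and patient covariates (age, sex,
severity) are out of scope, as are EVT transfer logistics and multi-patient
resource contention beyond the token.

The episode's hours class is frozen at door time (episodes last about an hour;
re-classifying mid-episode would complicate the graph for no measurable gain).

## Arrivals

A piecewise-constant-rate Poisson process over twelve two-hour clock blocks,
identical across days of week; block counts are Poisson with mean
`rate x 2h x scale` and times uniform within the block. The shipped rates
(`fixtures.TABLE_BLOCK_RATES`, arrivals/hour) put most arrivals between 08:00 and
20:00 and imply an analytic regular-hours share of
`(0.1008+0.1318+0.1395+0.1240) x 5/7 = 35.4%`; the weekday factor 5/7 is exact
because rates carry no day-of-week structure. The horizon starts Monday 00:00; a
year is 365 days; there is no warm-up (each episode is transient) and no censoring
(patients arriving before the horizon end run to completion). Site volume enters
through one multiplier per site (1.0, 780/3021, 405/3021), giving expected pooled
30-year treated counts of about 3021 / 780 / 405.

## Randomness and common random numbers

Every draw comes from a dedicated substream keyed by
`(base_seed, replication, patient_index, activity_id)`; arrival times and pathway
assignments have their own keys. Deleting an activity or scaling a duration
therefore leaves every other draw untouched, and sampling is one inverse-CDF
transform of a single uniform per draw, so `scale(d, k)` yields *exactly* `k`
times the original samples under the same seed. Consequences used by the tests:
scenario comparisons are variance-free at the patient level, no scenario can
increase any patient's DNT, and the decision-time reduction (R1) at the urban site
leaves the DNT stream byte-identical because the decision branch is almost surely
dominated by the prep branch. The truncated-normal family enforces its lower bound
by inverse-CDF truncation — identical in law to resampling out-of-range draws, but
without breaking the one-uniform-per-draw layout (and with no point mass at the
bound, unlike clamping).

## Scenarios

Pure transformations of a site config: P1 deletes the ED-bay transfer (successors
inherit its predecessors), P2 deletes the imaging→ED travel everywhere and swaps
the active tPA-prep law for the site's in-imaging variant, P3 moves EMS
registration to phase A (kept in the log for audit), R1/R2 scale the decision/prep
laws by 0.65. Codes a site already practices are no-ops. P-codes apply before
R-codes, making composition order-independent; with P2+R2 the 0.65 factor applies
to the in-imaging variant, i.e. the two prep reductions compound multiplicatively
(an explicit choice — the alternative, R2 relative to the original prep, would
make the combined scenario irreproducible from the single-code results). Configs
are tagged with their applied codes; re-applying an R-code raises rather than
silently scaling twice.

## Outcome statistics

Quantiles use numpy's linear-interpolation definition (the original modelling
tool's convention is unknown; one convention is simply fixed and documented).
Summaries pool the concatenated DNT sample over all replications — the quantile of
the pooled sample, not the mean of per-replication quantiles. Percentage
reductions are `100 x (baseline - scenario) / baseline` on the pooled median, IQR
width and 90th percentile. Their 95% CIs are percentile bootstrap over
replications (resampling whole replications with replacement within each arm,
10,000 draws by default): how the original study computed its intervals is not
stated, so a defensible, reproducible method was chosen — point estimates are
comparable, interval widths need not be. Mann-Whitney U uses exact enumeration for
tie-free samples with n ≤ 8 per arm, else the normal approximation with tie and
continuity corrections; the chi-square GOF is Pearson's statistic on k categories
with k−1 degrees of freedom. The replication-count analysis is the standard
sequential t-interval procedure (smallest n whose half-width is within a relative
precision of the pilot mean; 30 replications comfortably satisfies 5% at 95%
confidence for all shipped sites). A one-at-a-time `sensitivity_sweep` rescales a
single role and re-runs under common random numbers.

## Fixtures and calibration

The three site graphs are a minimal reconstruction consistent with how the sites
describe their practice: the urban site already keeps EMS patients on the
stretcher and pre-registers them, and already gives tPA in imaging *during regular
hours* (encoded as regular-hours prep = in-imaging variant and an imaging→ED
travel leg that exists out-of-hours only); the rural sites add a CT-technologist
call-in delay out of hours; the third site alone retains the ED-bay transfer and
post-door registration. The prep activity deliberately branches from
interpretation in parallel with the decision, because that series-parallel shape
is the only one that reproduces the observed scenario pattern: a decision-time
reduction alone does nothing at the urban site while decision + prep reductions
combine super-additively at the slow rural site.

The published per-activity duration tables are not available, so shipped
distributions are **calibrated stand-ins** (`provenance="calibrated"`): triangular
laws for expert-elicited in-hospital tasks, plus a lognormal stroke-recognition
delay for walk-in patients, which supplies the heavy upper tail that keeps the
90th percentile far above the median (walk-in strokes can sit unrecognized in the
ED; nothing in the improvement scenarios touches that delay, which is why the
90th percentile improves much less than the median). Shape ratios were tuned by
Monte-Carlo against the published baseline medians, IQRs, 90th percentiles and
scenario reductions; a final **global duration multiplier per site**
(`fixtures.SITE_DURATION_SCALES`, found by `calibrate_global_scale` with common
random numbers at seed 7, 30 replications, tolerance 0.05 min and frozen) pins
the baseline medians to the observed 50.0 / 40.1 / 74.0 minutes. One global
multiplier — not per-activity fitting — is used deliberately: per-activity values
are unidentifiable from three medians, and a uniform scale leaves every
percentage reduction invariant. Fresh seeds reproduce the calibrated medians
within about twice the calibration tolerance (sampling variation of a pooled
median over ~405–3000 patients). `load_sm1_distributions` replaces stand-ins from
a CSV transcription (`site, role, hours, family, params[, variant]`, slash-
separated parameters) and tags them `provenance="SM1"`; until then, site-level
baselines are matched by construction and scenario-level numbers are structural
approximations.

## What the synthetic conditions do and do not show

The generator reproduces the study's *conditions*: the time-of-day arrival
profile, the 80/20 pathway mix, the 35/65 hours split, the published treated
volumes, and scenario responses consistent with the published medians and
percentiles. It does not model day-of-week or seasonal arrival structure, onset
time, patient covariates, correlated durations, staff rosters or bed capacity —
so passing tests demonstrate the mechanics and the calibrated summary behaviour,
not patient-level realism. At the study's volumes (~100–3000 treated/year) the
protocol token is almost never contended; it is modelled because the system
described works that way, and tests exercise it at inflated volumes.

## Numerical choices

Time is real-valued minutes throughout; serialized outputs round to 3 decimals
but all statistics are computed at full precision. Simultaneous events resolve in
(door time, patient index) order. The engine is a sequential earliest-start
scheduler — exact for this model class because the capacity-one FIFO token is the
only shared resource, so no event calendar is needed. Bisection calibration starts
from the proportional guess `target/current` and brackets with bounded expansion;
it is deterministic given a seed. Degenerate inputs (empty replications at tiny
rural volumes) are handled by redrawing bootstrap resamples that contain no
patients and by NaN-propagating interval endpoints for undefined spread
reductions.

## Problem sizes

Default experiments are 30 replications x 365 days, matching the study design;
the full test suite (including the acceptance tests, which run every scenario at
full size) completes in well under a minute because a replication-year simulates
in ~20 ms.

## Known limitations

Scenario-level agreement with the published study rests on calibrated stand-ins
until the supplementary duration tables are transcribed; the published
per-scenario patient counts differ slightly across scenarios at one site (e.g.
780 vs 856), which fixed arrival streams cannot produce — runs here default to
common arrival streams, with `independent_arrivals=True` available; and printed
confidence intervals may differ in width from the bootstrap intervals computed
here even where point estimates agree.
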