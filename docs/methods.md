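# Methods

`matuku` packages the analysis workflow behind acoustic call-count
monitoring of the Australasian bittern (*Botaurus poiciloptilus*), a
cryptic wetland bird whose booming males are counted by ear: paired
observer/recorder survey simulation, rule-based minimum counts of calling
individuals, device-versus-observer calibration, an itemised cost model
for monitoring options, and simulation-based power for the sampling
design. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data do and do not establish.

## Survey simulation (`matuku.survey`)

A count station observes a population of calling agents. Each agent has a
bearing, a distance, an expected call-sequence rate per 15-minute session,
a characteristic boom count, and a source loudness. A session unfolds in
two stages:

1. **Emission.** Each agent emits Poisson(call_rate) call sequences at
   times uniform on [0, 900] s (the protocol fixes 15-minute counts; the
   arrival process is otherwise unconstrained, and a homogeneous process
   is the minimal choice). The boom count is drawn once per bird per
   session as 1 + Poisson(boom_mean − 1) — support ≥ 1, mean `boom_mean` —
   and repeated on every sequence. Holding it fixed within a session is
   deliberate: the observer rules treat boom count as an individual
   signature ("consistently different"), which only discriminates if the
   trait is stereotyped within a bird. An i.i.d.-per-sequence draw would
   make the boom criterion split single birds, destroying the minimum-count
   guarantee the rules are designed around.
2. **Detection.** Every emission is thinned independently per channel
   (OBS, MONO, STEREO) with that channel's detection probability, which may
   be a constant or a declining function of distance. Detected copies get
   wrapped-normal bearing jitter (default sd 5°, chosen to stress the
   10° criterion from both sides), a volume class, and — on the stereo
   channel — a left/right assignment.

**Volume classes** come from received intensity
`loudness × (200 m / distance)²` cut at configurable thresholds (defaults
1.0 and 0.25, i.e. class boundaries at 200 m and 400 m for a unit-loudness
bird); misclassification, with configurable probability, moves one class
up or down only — gross low↔high confusions are implausible for a trained
listener.

**Stereo channel.** The recorder's two microphones split the circle along
its heading axis: bearings strictly in the left half-plane map to `left`,
everything else — including bearings exactly on the axis, fore or aft — to
`right`. The on-axis tie-break is arbitrary but fixed and tested.

**Campaign composition** defaults to 137 sessions split 43 (three-way) /
80 (observer + mono) / 14 (observer + stereo), the season structure the
calibration assumes, with stations cycling over 40 station ids. Per-session
population sizes are Poisson with mean 3 calling birds and per-bird rates
average 3 sequences per session (so roughly 9 sequences heard per count).
These rates are illustrative: no per-session count distributions are
published for the motivating wetland, so the defaults are chosen to give
realistic non-degenerate counts, not to match a particular site.

Everything is driven by one `numpy` Generator per campaign, so all outputs
(including CSV exports) are bit-reproducible under a fixed seed.

## Minimum numbers of calling individuals (`matuku.assignment`)

Both estimators implement the field convention that ambiguity merges:
where it is uncertain whether one or two birds called, one is counted, so
the result is a *minimum* number of individuals.

**Observer rules** (`assign_observer`). The protocol's pairwise wording —
a call is a new bird if its bearing is more than 10° from any previous
call, or it is within 10° but in a different volume category, or within
10° with a consistently different boom count — cannot be applied literally
(the "any call previously heard" reading would make almost every call a
new bird once two birds are present). It is operationalised as incremental
clustering, which matches the intent of tracking distinct birds:

- calls are processed in temporal order against the current cluster set;
- a cluster accepts a call iff the circular bearing difference to the
  cluster's reference bearing (the circular mean of its members, folded
  into [0, 180]) is within the threshold; **and** the call's volume class
  has been seen in the cluster; **and** the boom count is not
  *consistently* different — operationalised as: the cluster has at least
  two members and none of its observed boom counts matches (a single
  observation cannot yet be "consistent");
- a single-member cluster may additionally absorb an *adjacent* volume
  class when the bearing difference is within half the threshold
  (`adjacent_volume_start`, on by default, off for the strict reading):
  one observation only loosely pins the category, and without the
  softening borderline volumes over-split;
- a call accepted by no cluster founds a new bird; if several clusters
  accept, the smallest bearing difference wins, ties to the lowest cluster
  id — every tie-break resolves deterministically and toward fewer birds.

Whether the boom criterion compares to the previous call only or to the
whole candidate bird is ambiguous in the field wording; the cluster-wide
reading is implemented. How observers tracked a bird whose bearing drifts
is also unspecified; the running circular mean is order-stable and
testable, but no further drift handling is attempted.

**Stereo-audible rules** (`assign_stereo_audible`). On stereo recordings
birds are distinguished only by the combination of volume class
(low/med/high) and ear (left/right), so the count is the number of
distinct pairs observed and can never exceed
`distinguishable_capacity(3, 2) = 6` — the structural ceiling of the
method, reached only when birds happen to spread over all six
combinations.

Both estimators are verified against independent brute-force
re-implementations on thousands of random sessions, and the zero-noise
minimum-count property (estimate ≤ number of birds that called) is checked
on simulated sessions.

## Device calibration (`matuku.calibration`)

Per recorder × processing option, each paired session contributes
(observer count, device count). Two summaries are fitted:

- **Spearman's rho** on tie-averaged ranks, with the p-value from the t
  approximation on n − 2 degrees of freedom (standard for n > 10; an exact
  permutation p would change nothing material at campaign sample sizes),
  plus **Fisher's z = atanh(rho)**. A constant margin raises a flagged
  `ZeroVarianceError` rather than returning an arbitrary number; in table
  assembly the correlation is reported as NaN while the slope is kept.
- **Regression through the origin**, y = b·x with x the observer count:
  b = Σxy/Σx², SE = √(RSS/(n−1)/Σx²), CI from the t quantile on n − 1
  degrees of freedom (one fitted parameter; a normal quantile is available
  by flag). The through-origin slope has a direct reading: with observers
  detecting (essentially) everything, b estimates the device's per-call
  detection ratio, and the simulation recovers a known thinning
  probability (0.67) to within Monte-Carlo error over 500 sessions.

Because VISUAL and AUDIBLE processing act on the same recorded channel,
the simulator gives them identical pairs unless their detection
probabilities are configured apart; the table machinery treats them as
separate options regardless, mirroring how real processing differences
enter. The published field correlations themselves are not reproducible —
the underlying pairings were never deposited — so the tests validate the
machinery by parameter recovery instead.

`individuals_calibration` applies the same statistics to minimum
*individual* counts: stereo-audible counts against observer-rule counts
(or simulation truth). The capacity cap means device counts saturate at
six while observer counts can exceed it; with many birds this drags the
slope below one, which is the expected signature, not an error.

## Cost model (`matuku.costs`)

Five options for the same regime — 15-minute counts at 40 stations on six
consecutive nights, costed over two years — are built from line items:
purchase, file processing or paid count time, deployment, driving to/from
site, driving around the site, programming (or observer briefing), and
vehicle running. Default rates: wages NZ$25/hr, NZ$0.77/km, 130 km and
2 hr per return trip, 45 min per circuit of the wetland; mono units
NZ$300 (2.5 min programming, 2 min deployment, timer-driven so one deploy
and one retrieval trip a year), stereo units NZ$600 (3 min programming
and servicing before each occasion, 10 min deployment, a trip per
occasion), observers briefed 30 min before each occasion, paid for count
time, travel and circuits individually, with one vehicle per five
observers.

**Rounding.** All arithmetic is on unrounded values; display rounds half
away from zero at the end. This is load-bearing: 112.5 → 113 and
37.5 → 38 at the line-item level, and the observer year total displays
25,821 even though its rounded line items sum to 25,822.

Three parameters are calibrated to the published cost table rather than
derived, and are kept as explicit, overridable configuration:

- the mono option charges **one** return trip as wages (NZ$50) while the
  vehicle runs **two** trips (NZ$200) — the stated two trips would give
  NZ$100 of wages, which is not what the table shows;
- stereo deployment accrues once per year (NZ$167) with the per-occasion
  servicing burden carried by programming (NZ$300), although the prose
  says deployment recurs per occasion;
- the stereo year-two vehicle cost uses a fixed override of 554.00, which
  is not derivable from 6 × 130 km × NZ$0.77 = 600.6.

In each case the table is treated as canonical over the prose. Currency is
unitless "NZ$-like"; there is no discounting, no uncertainty on costs and
no design optimisation. `percent_saving(a, b) = 100·(1 − a/b)` on
*unrounded* cumulative costs, displayed to the whole percent — this is how
the headline 73% (mono-visual vs observers) and 46% (stereo vs observers)
figures arise. The qualitative value matrix (call-rate index / estimate of
numbers / public participation, each easy / with_work / no) is fixed data,
not computed.

## Power analysis (`matuku.power`)

`estimate_power` answers: under a stations × occasions design, what is the
probability of detecting a proportional change in the session calling
rate? Each replicate simulates a baseline and a changed campaign of
session-level counts and applies a two-sided permutation test on the
difference in mean counts — distribution-free, matching the non-normality
of call-count data, and self-contained. Session counts are drawn directly
as Poisson(rate): per-agent emissions are Poisson, so the session total
over any population is exactly Poisson in the aggregate, and skipping the
per-call object construction keeps hundreds of replicates in seconds.

The permutation p-value includes the observed statistic in the reference
set, so p ≥ 1/(n_perm + 1); with the default n_perm = 199 the achievable
p-values are k/200, making rejection at p ≤ 0.05 exactly calibrated under
the null. An exhaustive mode (`n_perm=None`) enumerates all splits for
small samples and is the oracle in the tests. Rejection uses p ≤ α.

Defaults (baseline 9 sequences/session, α = 0.05, 500 replicates) are
illustrative: the variance structure behind any particular wetland's
power figure — between-station and between-night heterogeneity — is
unknown and not modelled, so the module is a transparent re-derivation
tool for planning, not a reproduction of any prior power claim. Under
these defaults the 40 × 6 design reaches ≈ 0.88 power for a ±10% change,
consistent with the > 80% planning threshold such regimes are built to.
The Monte-Carlo standard error √(p(1−p)/R) is reported alongside every
estimate.

## Problem sizes and runtime

Test and acceptance runs use: campaigns of 137 sessions (composition
checks, calibration tables), 500 three-way sessions for detection-ratio
recovery, 1,000 random small sessions (≤ 20 calls) for oracle
equivalence, and 500 replicates × 199 permutations for test calibration
and power. These sizes put Monte-Carlo error comfortably inside the
asserted tolerances (e.g. slope recovery to ±0.05 with simulation SE
≈ 0.007) while keeping the full suite under a minute on one CPU.

## What passing tests do and do not show

The generator emulates the *statistical structure* the analysis assumes —
paired channels thinned from common emissions, bearing/volume noise,
capacity-limited stereo discrimination — not real soundscapes: no overlap
or masking between simultaneous calls, no temporal clustering of booming,
no between-night or weather-driven rate variation, no observer skill
differences, stationary birds within a session, and boom counts perfectly
stereotyped within a bird. Passing tests therefore establish that the
estimators, statistics and cost arithmetic are implemented correctly and
behave as designed under their own assumptions; they say nothing about
how well those assumptions fit any particular wetland, which is a field
question.
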