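# Methods

`sagame` analyses a SAGAT-style situation-awareness video game: players watch
traffic clips filmed from a cyclist's perspective, each clip is suddenly
masked, 2–3 screen locations are highlighted, and the player selects those
that held a hazard (an overt road user or a covert occlusion) at the moment
of masking. Because no raw participant data ship with the package, every
analysis stage is paired with a synthetic generator with known parameters,
so the whole pipeline is testable by parameter recovery.

## Stimulus bank

The default bank reproduces the game's structure: 30 game clips plus 3
practice clips; 79 probed game locations composed of 33 overt targets, 12
covert targets and 34 empties (prevalence s = 45/79 ≈ 0.57); per clip 2–3
locations holding 1–2 targets. The location-count arithmetic is fully
determined by the totals (79 locations over 30 clips forces 19 three-location
and 11 two-location clips; 45 targets force 15 two-target clips); the only
free allocation choice — how many two-location clips carry two targets — is
drawn uniformly over the values that keep one-target clips in the majority
among two-location clips, a structural property of the original stimulus
set that players could in principle exploit. Game-clip durations are
truncated-normal (sd 5.08 s, bounds 4.81–24.19 s) and shift-rescaled so the
sample mean is exactly 11.47 s; total watch time is therefore 344 s
(5 min 44 s). Coordinates are normalized to the unit square (origin
top-left) so nothing depends on a physical display. The published
composition is attributed to the game clips only; the three practice clips
get a fixed composition (overt+empty, covert+empty, overt+covert+empty) so
every location kind also occurs in practice.

## Observer model

Each simulated participant is an equal-variance SDT observer: evidence at an
empty location ~ N(0, 1), at a target ~ N(d′, 1); the location is selected
when evidence exceeds a criterion λ measured from the noise mean. d′, λ and
the mean response time are phase-dependent (phases = game-clip positions
1–10 / 11–20 / 21–30 in the participant's randomized order), which
implements learning as a step trend; practice clips are played with
start-phase parameters. Response times are lognormal with phase means
4.82 → 4.15 → 3.47 s (start/end from the reported group-collapsed means, the
middle interpolated) and shape 0.4. An optional lapse rate replaces a
selection with a fair coin, used only to stress-test estimators.

Default profiles encode the reported per-phase group means: children d′
(0.88, 1.06, 1.43) with criteria (0.24, 0.28, 0.50); adults d′ (1.74, 1.82,
2.04) with criteria (0.68, 0.76, 0.88). By construction the expected raw hit
and false-alarm rates then match the published phase × group table exactly
(e.g. children at start: Φ(0.88 − 0.24) ≈ 0.74 hit rate, Φ(−0.24) ≈ 0.41
false-alarm rate). Between-subject heterogeneity is a common Gaussian shift
of d′ (sd 0.5, floored at 0.05) and λ (sd 0.3) across phases. These
generative sds are deliberately smaller than the printed between-subject
sds (~0.70 for d′): a per-phase window has only ~26 locations, so the
printed sds include binomial estimation noise of roughly 0.5 sd-units in d′;
with the chosen generative values the *realized estimate* sds land near the
printed ones.

Gaze streams are sampled at an effective rate drawn uniformly in
[10, 30] Hz, mimicking a head-mounted tracker whose eye camera drops
frames. With probability `p_look` (children 0.35, adults 0.55 — the reported
percentage of targets looked at) the trace enters the analysed AOI
max(1, Poisson(glance_rate)) times, the first entry after a lognormal
latency from target appearance (means 2.48 / 1.97 s), each with a lognormal
dwell (means 0.74 / 1.16 s per glance) truncated at the mask; otherwise, and
between glances, the trace follows a center-biased AR(1) walk that is pushed
out of the AOI if it strays in. Two deliberate simplifications: there are no
saccade kinematics (the generator only needs to exercise glance detection
and recovery), and because the published dwell statistic is *total* dwell
per looked-at target while the generator's parameter is per-glance dwell,
the simulated total dwell exceeds the per-glance mean by the glance-count
factor. Likewise E[max(1, Poisson(r))] slightly exceeds r, so detected
glance frequency sits a little above the nominal rate. Neither affects the
group orderings the generator is meant to reproduce.

The counting-span generator runs the schedule of set sizes 2..8 with three
trials per size (105 tallies when completed). A tally is recalled correctly
with probability 1 − noise when the set size is within the observer's
capacity, decaying by 0.25 per item beyond capacity; the task stops early
after three consecutive trials whose recalled set is not exactly correct.
Note the early stop truncates exactly the low-credit trials, so
partial-credit scores of early-stopping observers are compressed upward
relative to a full schedule: the defaults (children capacity 2 / noise 0.2,
adults capacity 6 / noise 0.05) reproduce the reported child–adult contrast
(Cohen's d ≈ 3) rather than the absolute group means, which are not
attainable under this stop rule.

## Performance measures

Confusion counts are tallied per participant and window (phase or overall,
game clips only, overt and covert collapsed into "signal"). Rates get the
log-linear correction — 0.5 added to hit and false-alarm counts, 1 to signal
and noise trial counts — unconditionally, so they are always interior.
Then:

- d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate);
- observed criterion λ_obs = −Φ⁻¹(false-alarm rate). The sign convention is
  the conventional noise-axis criterion: a conservative responder (few
  selections) has a *positive* criterion. This is the only form consistent
  both with the published table (41% false alarms alongside a positive
  observed criterion) and with the optimal-criterion formula below, whose
  s = 0.5 case is the positive midpoint d′/2;
- optimal criterion λ_opt = d′/2 − logit(s)/d′ with s the realized target
  prevalence of the participant's window (clip order is randomized, so phase
  composition varies by participant; overall s = 45/79). When an estimated
  d′ is exactly 0 the optimal criterion is undefined and λ_opt and bias
  propagate as NaN; inferential stages then use complete cases;
- response bias = λ_obs − λ_opt (negative = biased toward selecting);
- accuracy = proportion of locations answered correctly (uncorrected);
  its logit is used as the regression response, with a (k + 0.5)/(n + 1)
  shrink applied only at accuracies of exactly 0 or 1, mirroring the
  log-linear philosophy;
- PCU = mean over administered trials of the per-trial proportion of
  positionally correct tallies (trials cut off by the early stop are not
  averaged in).

Windows use pooled counts over their locations, not per-clip averages.

## Gaze metrics

AOIs are circles interpolated linearly between keyframes, live from the
moment the target is identifiable until the mask. The event criterion —
which the underlying AOI method leaves open — is: a glance is a maximal run
of valid in-AOI samples lasting ≥ 100 ms, with runs separated by gaps
≤ 75 ms merged; invalid samples break runs but count toward gap duration.
Both thresholds are configurable. A participant is excluded when the mean
nine-point calibration error exceeds 2°, a clip when its effective sample
rate (n − 1)/(t_last − t_first) is below 5 Hz; the visual-inspection
exclusion used with real recordings is an optional manual flag, not an
algorithm. Per participant, four statistics are computed over the 10
analysed targets: percent looked at, and — over looked-at targets only —
mean glance count, mean first-glance onset latency from appearance, and
mean total dwell. First-glance latency uses glance onset (the first sample
of the detected run). The default AOI set picks the most off-center overt
target in each of 10 distinct game clips (off-center so glances are
distinguishable from looking in the direction of motion), visible for the
final 6 s before the mask.

## Inference

Welch's unequal-variances t-test with pooled-sd Cohen's d (the d variant is
not determined by the published values; an unpooled variant is available
via a flag). The learning analyses use a two-way mixed (split-plot) ANOVA —
between-subject group, within-subject phase — computed from closed-form
sums of squares, with partial η² = SS_effect/(SS_effect + SS_error) and the
Greenhouse–Geisser ε from the eigenvalues of the double-centered pooled
within-group covariance of the phase measures, ε = (Σλ)²/((k−1)Σλ²) ∈
[1/(k−1), 1]; corrected and uncorrected p-values are both reported for
within effects. The implementation is cross-checked against
`pingouin.mixed_anova` in the test suite. Linearity of the phase trend is
tested by a per-participant (−1, 0, +1) contrast with a one-sample t
(per-contrast error term); a zero-variance contrast is flagged degenerate
rather than tested. Regressions are OLS (statsmodels) on logit accuracy
with adjusted R²; nested models are compared by
F = (ΔR²/Δp)/((1 − R²_full)/(n − p_full − 1)). Two-sided p-values at
α = 0.05 throughout and no multiple-testing correction, matching the
reporting conventions the pipeline mirrors.

## Pipeline and reproducibility

`run_study` fans a single root seed out to every stage by stable hashing of
(root, purpose-label), so adding a stage never perturbs existing streams and
identical config + seed yield byte-identical reports. The report carries the
config hash, seed and package version; stage boundaries log counts
(participants, clips, exclusions) so attrition is auditable. Serialized
tables are delimited text with round-trip-exact floats; the report JSON has
a schema version checked on read.

## What passing tests do and do not show

The synthetic cohort reproduces the *structure* of the original data —
composition, scoring arithmetic, group orderings in accuracy, d′, gaze, and
the sign and rough size of the accuracy–points correlation — because those
are consequences of the generative model seeded with the published group
means. It does not reproduce, and cannot validate, the original inferential
statistics (exact F, t and p-values), which depend on the real participants;
nor does it model criterion adaptation to feedback over phases, touch
interaction, or motivational dynamics. Gaze simulation covers only the 10
analysed AOI targets. Problem sizes in the test suite (300-observer
recovery runs, 100 cohort replicates, 1,000-rep null calibrations) were
chosen so that Monte-Carlo error is small relative to the tolerances being
asserted.
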