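# Methods

`geovalid` implements and stress-tests a complete measurement chain for a
GPS-derived index of daily activity — the Number of Places Visited (NPV)
— together with the psychometric and statistical machinery used to
establish its convergent and nomological validity against self-report
methods. Because the raw participant data behind the original validation
study are not publicly deposited, the package pairs every analysis
component with a synthetic-data generator that retains ground truth, so
each stage can be audited by recovery rather than by re-running the
original sample.

## The measurand

NPV counts *visit events* over a fixed observation window of four full
days (two weekdays, two weekend days): leaving home in the morning and
returning at night contributes two home visits. Three instruments
measure the same quantity — an end-of-day diary, a map-based
reconstruction performed at study end, and a body-worn GPS tracker
recording position once per second while it detects movement.

## GPS chain

**Stop detection.** A stop is a maximal episode of at least
`min_dwell_s` = 600 s during which every retained fix lies within
`eps_m` = 50 m of the episode's running centroid. The 10-minute dwell
threshold is the substantive definition; the 50 m radius
operationalizes "no detectable change in location" under consumer-GPS
scatter and is configurable. The sweep is linear-time: a window grows
while each new fix stays within `eps_m` of the running centroid and is
emitted when its dwell reaches threshold (boundary inclusive).

**Gaps.** The tracker records only while moving, so silence implies
stationarity. A recording gap counts toward dwell when the resuming fix
lies within `gap_dwell_eps_m` (default = `eps_m`) of *any of the last
five* retained pre-gap fixes. The any-of-five rule is deliberate: with
motion-triggered dropout the pre-gap window tail mixes a handful of
true dwell fixes with approach fixes still tens of meters out, and a
single noisy bounding fix misjudges the pre-gap position often enough
to sever real dwells. Comparing against several recent positions makes
gap bridging robust to single-fix noise without loosening the radius.

**Anomaly screen.** A fix is flagged when its speed is implausible
(recorded or implied speed above `max_speed_mph` = 75) *and* its
heading swings by more than `turn_deg` = 90° (circular difference)
relative to the previous fix. Requiring both conditions spares fast
but straight highway travel. Flagged fixes are excluded from stop
formation; a stop whose time span is majority-flagged is dropped
outright. Heading uses recorded values when present, otherwise
successive travel bearings.

**Place classification.** The original protocol resolved ambiguous
stops by human inspection of maps. That is replaced by deterministic,
audited proxies: consecutive stops with centroids within
`merge_identical_m` = 30 m are one visit (same location); within
(`merge_identical_m`, `merge_building_m` = 75 m] they merge as one
building/yard; a stop is dropped as in-transit when its inbound and
outbound travel bearings agree within `transit_bearing_deg` = 30° and
its dwell is at most `transit_max_dwell_s` = 900 s (a traffic queue, a
red light). Every stop receives exactly one audit label; only
non-consecutive revisits count repeatedly, matching the diary
instruction. Visits are credited to the local calendar day of arrival
(the configured IANA timezone decides weekday/weekend; Saturday and
Sunday are the weekend), and daily counts aggregate over the declared
2+2-day calendar into weekday, weekend and 4-day NPV, with the
conservation identity weekday + weekend = total enforced by
construction.

## Factor scores

The Active Lifestyle (AL) composite is the unit-weighted mean of
z-scored Positive Affect, Mini-K, Conscientiousness, Extraversion and
Agreeableness totals; Sedentary Lifestyle (SL) averages z-scored BDI,
CES-D, Negative Affect, reversed Satisfaction-with-Life and Neuroticism.
Standardization uses the analysis sample's own moments (ddof = 1),
recomputed after any row filtering. A score is emitted when at least 3
of 5 indicators are present (the mean of the available ones); openness
is accepted in input tables but excluded from AL. Cronbach's alpha is
provided as a diagnostic. Higher SL means a more depressive/neurotic
profile; the SWL reversal enforces that sign convention.

## Split-plot GLMs

The outcome table holds up to six rows per subject (2 periods × 3
methods). Time is coded −½ (weekday) / +½ (weekend); the planned method
contrasts are C1 = (Diary +1, Google −1, GPS 0) and C2 = (Diary +½,
Google +½, GPS −1) — orthogonal and centered. With the ±½ Time coding
the final model's intercept estimates the grand per-period mean and the
Time coefficient the weekend-minus-weekday difference; contrast and
Time rescalings leave all F tests unchanged.

Variance is partitioned by Type-I (sequential) sums of squares: terms
enter in a declared order (AL-first or SL-first for the two causal
orderings; between-subjects terms AL, SL, AL×SL, SID before the
within-subjects block Time, C2, C1, the interaction series, and the
SID-interaction error terms), and each term's SS is the squared
projection of the outcome onto the orthogonal complement contributed by
that term's columns. Degrees of freedom are realized column-rank
increments on the actual (possibly unbalanced) design, so missing cells
shrink DDFs exactly as they should. Each tested term is referred to its
declared error stratum — {AL, SL, AL×SL} to SID; {Time and its
covariate interactions} to Time×SID; the C2 (C1) family to C2×SID
(C1×SID); SID, the Time×contrast terms and the SID interactions to the
residual — in the expected-mean-squares tradition. A rank-deficient
denominator raises an explicit error naming the stratum rather than
returning a misleading F. No mixed-model (REML) refit and no
Satterthwaite correction are attempted; reproducing the hierarchical
partition is the point.

Effect sizes: semi-partial R² = SS / corrected total SS; partial R² =
semi-partial / its broad stratum's (between- or within-subjects)
semi-partial total, so each stratum's partials sum to one and the two
stratum totals sum to the model R². The correlation panels use
pairwise-complete Pearson r with two-sided p from the t transform and a
Fisher-z 95% CI (the CI method is a documented choice; no standard
symmetric-in-z method reproduces every interval in the original
report). p-values are two-sided with no multiplicity correction. The
missingness screen dichotomizes task completion and tests association
with covariates (Welch t for continuous, chi-square for categorical);
it reports only — no imputation anywhere.

## Synthetic-data generator

The generator emulates the full study. Per subject, latent (AL, SL) are
standard bivariate normal with correlation −0.30. True period-level NPV
follows `intercept + b_AL·AL + b_SL·SL + b_Time·Time + u_s + ε` with
defaults intercept 11.87, b_AL 1.79, b_Time −3.68, b_SL 0, subject SD
2.5 and residual SD 1.5, rounded and floored at zero (`discretize`
turns this off for exactness checks). The error scales were set so the
zero floor binds on well under 1% of cells: a binding floor would bend
the linear structural model the analysis assumes. Period counts split
binomially across the period's two days.

Each day's count becomes an itinerary of dwells (duration 20–30 min,
all comfortably above the 10-minute stop threshold) at places laid out
on a jittered grid with ≥ 250 m separation (safely beyond the 75 m
merge radius), scheduled inside an 08:00–22:00 local window with travel
slack so segments never overlap; consecutive entries never repeat a
place, and each day starts at a different place than the previous day
ended so overnight recording gaps cannot weld two distinct visits.
Trajectories are rendered at 1 Hz along straight travel segments
(15 mph) with Gaussian positional noise; while dwelling the
motion-triggered device either records nothing (default) or jittered
fixes. After the final dwell a departure segment is rendered — the
device records again when the subject eventually moves — which closes
the last dwell's observation window.

Anomalies are single-fix multipath spikes: a teleported position
implying far over 75 mph whose bearing deviates at least 120° from the
preceding travel direction (uniform in [120°, 180°], either side). The
spike model is matched to the screen's definition of an anomaly —
impossible speed in a discontinuous direction; a spike aligned with the
direction of travel is indistinguishable from fast driving for any
single-fix rule and is out of scope. Insertions are spaced at least
three fixes apart so each spike and its return fix are flagged as a
pair.

Self-reports default to truth plus independent zero-mean Gaussian
observation error per method (SD 3.0 for the self-reports, 2.5 for the
GPS channel at the statistical level), consistent with the original
finding of no systematic mean differences between methods. Recall
error (binomial thinning with probability `p_recall`, plus a Poisson
false-report process) is available as an explicit sensitivity knob; it
is mean-biased by construction, which is exactly why it is not the
default: the convergent-validity sweep varies it deliberately, while
parameter-recovery studies require an unbiased observation model.
Missingness is MCAR per task (default 0.2 for each NPV method, 0.12 per
questionnaire scale), with the 0/1 completion matrix retained for the
screen. Everything is driven by one `numpy` Generator seed;
re-running with the same seed reproduces every output byte.

Questionnaire indicators are generated as `λ·latent + √(1−λ²)·noise`,
rescaled to realistic instrument means/SDs and clipped to each scale's
possible range; SWL loads negatively on SL (λ between 0.59 and 0.91 in
magnitude across indicators).

**What the generator does not emulate.** Road networks and realistic
routing, circadian structure, MNAR missingness, device cold-start
behavior, urban-canyon noise correlation, and shared method variance
between the two self-reports (their errors are independent given
truth, so simulated self-report pairs do not correlate more highly with
each other than with GPS, as the original data did). Passing recovery
tests therefore demonstrates correctness of the chain under a
well-specified measurement model, not robustness to every field
condition.

## Simulation study sizes and numerical choices

Recovery and calibration studies use: 50 subjects for end-to-end GPS
NPV recovery (noiseless → exact; 10 m noise with dropout → ≥95%
observed ≈99%), 20 subjects for anomaly invariance, 200 random small
designs for the engine-vs-nested-refit oracle (agreement to ~1e-14
relative), 200 replicates at n = 96 for coefficient recovery and 500
for the SL type-I rate — sizes chosen to make Monte-Carlo error small
relative to the effects being checked while keeping a full run in tens
of seconds. Rank decisions use a relative singular-value tolerance of
1e-8 on each term's residualized block after two projection passes
(classical Gram–Schmidt twice) for numerical stability. Dwell exactly
equal to the threshold counts as a stop; heading differences are
circular; duplicate timestamps keep the first occurrence and are
counted in the parse log.

## Known limitations

The in-transit and same-building rules are geometric proxies for human
map inspection and inherit its ambiguity near their thresholds; stop
centroids under motion-triggered dropout rest on few fixes and are
correspondingly noisier than under continuous recording; the
split-plot engine deliberately reproduces a fixed-effects,
stratum-based analysis rather than a modern mixed model; and Fisher-z
intervals are approximate at the small per-cell n that pairwise
deletion can produce.
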