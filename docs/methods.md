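# Methods

This note records the models, parameter choices, and numerical conventions
behind `frailsense`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model and preprocessing

Input is tri-axial chest acceleration in g at a nominal 50 Hz. Axis
convention: axis 0 vertical (cranio-caudal), axis 1 frontal
(anteroposterior, positive toward the back), axis 2 lateral. Upright posture
places gravity on the vertical axis; supine places it on +frontal.

Timestamps must be strictly increasing and within ±16 g (sensor-range
guard). If the observed rate deviates from nominal by more than 1 %, the
signal is linearly interpolated onto the nominal grid so that the 300-sample
epoch count stays meaningful; within 1 % the samples are used as-is.

High-frequency content that cannot originate from body movement is removed
with a one-level Daubechies DWT (default `db4`, order configurable): at
50 Hz a single dyadic split lands exactly at 12.5 Hz, so zeroing the detail
band and reconstructing realizes the 12.5 Hz cut-off while preserving DC
(gravity). Measured on pure tones, a 20 Hz tone is attenuated by ~52 dB and
a 1 Hz tone is preserved to 0.1 %. MAD is computed on the filtered norm.

Epochs are non-overlapping 6-s windows aligned to the recording start; a
trailing partial epoch is dropped, never zero-filled. All MAD values are in
mg (1 g = 1000 mg); input CSVs are in g and converted once.

## Wear validity

Minute-level MAD is the arithmetic mean of the 10 epoch MADs in each fully
covered minute (partial edge minutes are dropped; a max-aggregate variant is
a one-line configuration change).

Non-wear detection scans left to right: a run grows over consecutive
zero-MAD minutes, absorbing interior blocks of minutes with MAD below
20 mg as long as the cumulative absorbed count stays ≤ 2 and a zero minute
follows (a run always starts and ends on a zero minute). When a third
interruption is reached the run closes and a fresh run, with a fresh
interruption budget, starts at the next zero minute. Completed runs of
≥ 90 min are non-wear. The union-of-windows alternative (flagging every
≥ 90-min window with ≤ 2 interruptions) was rejected: it lets three
interruptions inside a long gap remain non-wear, contradicting the split
semantics of the rule.

"No MAD" is implemented as minute MAD ≤ 0.5 mg. A motionless sensor yields
exactly constant gravity in theory, but any low-pass filtering leaves
float-precision residue (~3·10⁻⁵ mg) and smears the on/off-body
discontinuity into the first gap minute (~0.1 mg). The 0.5 mg floor sits two
orders of magnitude above that residue and a factor ~4 below the ~1.7 mg
noise-floor MAD of a worn but motionless sensor, so the dichotomy is
unambiguous on both sides.

Days are calendar days on the recording's local clock (the recording carries
a start-of-day offset). A valid day has ≥ 480 wear minutes; subjects need
≥ 2 valid days, and exclusions are classified as: no wear at all ("forgot
the sensor"), wear present but no valid day ("low wear time"), or fewer
than 2 valid days.

## Posture and stepping

Step detection band-passes the vertical axis by retaining the DWT detail
levels overlapping 0.5–3 Hz (at 50 Hz: levels 4–6) — the cadence band of
normal-to-slow elderly gait (30–180 steps/min) — then picks local maxima
with amplitude ≥ 0.1 g and a 0.2 s physiological refractory spacing. Both
the band and the threshold are configuration values; recovery tests are
against generator ground truth, not against the constants.

Walking bouts are maximal runs of ≥ 3 steps with consecutive gaps ≤ 2.5 s
(≈ the slowest continuous ambulation); shorter runs are incidental steps,
not walking. Bouts are padded by half a median step period so the bout
covers the strides.

Posture is classified per second. Lying: 1-s-averaged vertical gravity
magnitude < 0.4 g (≈ 66° trunk tilt). Remaining upright time is split into
sitting vs standing by a state machine, because a chest sensor cannot
separate the two static postures by gravity alone: sit-to-stand /
stand-to-sit transitions appear as transient forward-lean signatures in the
frontal–vertical plane (|frontal| peaks ≥ 0.45 g, ≥ 3 s apart, ≥ 3 s from
segment edges to avoid lying-boundary ramps), and each detected transition
toggles the state. Anchors resolve the initial state: a segment bordering a
walking bout starts/ends standing; a segment following lying starts sitting;
an unanchored segment defaults to sitting with a logged warning. This
detector is an original realization of the pattern-change idea; its exact
features are a design choice of this package.

Per-day bout statistics assign each bout to the calendar day containing its
midpoint (bouts are not clipped, keeping "longest unbroken" unbroken across
midnight). Posture percentages use the day's classified time as denominator
— identical to the share of 24 h on fully covered, fully worn days, and
still summing to 100 on partially covered edge days. The wear-time
denominator variant is available by re-running the behavior block without
the in-bed exclusion.

## Sleep

For each night, the in-bed interval is the longest block within the
21:00–11:00 nocturnal window whose minutes are ≥ 80 % lying; maximal lying
runs are greedily merged while the merged block keeps that dominance. The
window and the 80 % criterion are package choices; nights with no ≥ 60-min
block are skipped with a warning.

Within the in-bed interval only, each minute is scored by a transparent
logistic rule on three features: minute MAD (mg), the rolling 7-min SD of
minute MAD, and a lying-position-change indicator. Default weights
(−3.0, 0.12, 0.04, 0.8) were calibrated once against the synthetic
generator's ground truth (wake ⇔ probability ≥ 0.5, i.e. roughly
MAD ≳ 25 mg for an isolated quiet minute); they live in configuration, not
code. SOL counts to the first sleep minute; WASO is wake between first onset
and last offset; SE uses the onset-to-offset span as denominator — the
literal reading of its definition — with a time-in-bed denominator available
as a sensitivity switch. SOL + TST + WASO + terminal wake = TiB by
construction.

Lying position per minute comes from the dominant horizontal-plane gravity
component (nearest-axis rule at ambiguous angles): +frontal supine,
−frontal prone, lateral dominant → side (left/right pooled as "sides").
Minutes in bed that are not lying-dominated carry no position, so
supine + prone + sides ≤ 100 % of TiB.

## Feature set and units

Thirty parameters in four blocks (sleep 8, activity pattern 10, stepping 3,
activity behavior 9 + guideline flag); the canonical names, units, and
descriptions are in `features.FEATURE_DICTIONARY`. Behavior bouts are
maximal runs of same-level wear epochs; totals and percentages cover wear
time excluding the nocturnal in-bed interval; sedentary/light totals are in
hours, MtV in minutes, medians in seconds; steps are reported in thousands
with the raw count retained. The guideline flag is total MtV ≥ 42 min/day
(the daily equivalent of 300 weekly minutes, ⌊300/7⌋). "Median activity" is
the median bout duration in seconds for behavior levels and the median step
count for stepping bouts.

## Statistics and models

Group contrasts (non-frail vs pre-frail, pre-frail vs frail) come from an
OLS model with group indicators (ANCOVA covariates configurable; none by
default), tested against the 3-group residual variance. The default
post-hoc is unadjusted pairwise contrasts (LSD); the name "Tukey LSD"
conflates two procedures, and since exactly two contrasts are reported the
unadjusted form is the faithful default, with a studentized-range
(`tukey_hsd`) switch for sensitivity. Categorical variables use the
two-sided Fisher exact test. Cohen's d is reported as a magnitude with
(n−1)-weighted pooled SD.

Selection: filter (both contrasts p < 0.05 and d ≥ 0.4 — the two-contrast
"starred" reading), then embedded (single-feature decision-tree one-vs-rest
AUC > 0.7, 5-fold CV on the whole dataset, as the selection protocol
prescribes). Models: CART trees, max depth 3, min leaf 5 — shallow to match
the ~150-subject scale — with stratified 5-fold CV and a fixed default seed;
AUC is the Mann–Whitney probability with half credit for ties;
sensitivity/specificity SDs are per-fold (a bootstrap alternative was not
pursued). Quartile-based Fried criterion flags use linear-interpolation
quantiles with an inclusive boundary; identical values yield no flags.

## Synthetic data: what it emulates and what it does not

**Signals.** `sample_schedule` tiles 48 h (default start 20:00, so both
nocturnal windows are fully covered and the first evening is an invalid
partial day) with sitting, quiet standing, light activity, vigorous
activity, walking bouts with explicit step times, nights with programmed
SOL/WASO/terminal-wake and lying-position segments, and optional
minute-aligned non-wear gaps. Every programmed total (steps, activity
minutes, sleep structure, position shares) is recoverable from the schedule
in closed form. `render_signal` realizes it at 50 Hz: gravity follows the
posture orientation; steps are 0.5 g raised-cosine bumps whose band-passed
fundamental (~0.3 g) peaks at the programmed step times; light (0.078 g) and
vigorous (0.236 g) movement oscillate at 4.2/4.8 Hz — above the step band,
below the 12.5 Hz cut-off, with amplitudes chosen so the epoch MAD of
|1 + a·sin| (≈ 2a/π g) lands mid-band (~47 and ~140 mg); restless in-bed
wake oscillates along the gravity axis (~42 mg); transitions render a 50°
forward-lean half-sine; non-wear is noiseless constant gravity; everything
else carries 3 mg Gaussian noise. Consequences worth knowing: rendered
walking is moderate-to-vigorous by construction, and daily MtV truth is
walking time plus programmed vigorous minutes.

The renderer does not attempt biomechanically realistic gait waveforms,
postural sway, or free-living variability. End-to-end recovery (steps within
2 %, sleep quantities within 5 min, posture-second recall ≥ 90 %, position
shares within 2 %, non-wear gaps exact) therefore demonstrates internal
consistency of the detectors under the stated signal model — not field
accuracy on real recordings.

**Cohorts.** `sample_cohort_features` draws per-group correlated Gaussians
matching published group means ± SDs for 42/78/33 non-frail/pre-frail/frail
older adults, with within-block correlation 0.5 (a documented assumption,
configurable) and rejection sampling of rows outside physical bounds
(non-negative durations, percentages in [0, 100]) — i.e. a truncated
multivariate normal; residual violations after the resampling cap are
clipped. The guideline flag derives from the drawn MtV minutes, which
reproduces the published compliance gradient (~50/16/3 %). Two limitations
are structural: truncation materially shifts marginals whose published SD
exceeds their mean (such quantities are heavily skewed in reality, which a
Gaussian cannot carry), and Gaussian marginals with block correlation do not
reproduce the joint separability of real cohorts — cross-validated
discrimination on these tables (combined-model AUC ≈ 0.68) is accordingly
weaker than on real data, and borderline features flicker in and out of the
p/d selection across seeds. The replication suite measures and reports both
effects; they bound what the calibrated cohorts can certify.

**Exclusion fixture.** 163 two-day minute-MAD traces: 153 clean (with
sub-threshold off-body gaps), 3 with under-8-h wear on every day, 5 with
exactly one valid day, 2 entirely unworn. Counts are deterministic across
seeds; traces are not. The fixture operates at minute resolution because
the wear rules are minute-based.

## Numerical conventions and degenerate inputs

Zero-variance features yield NaN p-values with a warning; zero pooled SD
makes Cohen's d undefined; constant features score AUC 0.5; a night with no
sleep minutes has SOL = TiB and undefined SE; absent bouts of a posture or
level yield 0 % and missing bout statistics; missing Fried flags yield a
missing status (complete-case). Cut-point and threshold comparisons follow
the printed inequality directions verbatim (sedentary < 20 ≤ light < 90 ≤
MtV; non-wear ≥ 90 min; valid day ≥ 480 min; guideline ≥ 42 min;
interruptions strictly between 0 and 20 mg). Feature CSVs round-trip at
full float precision.

## Problem sizes used in the test suite

The default verification runs ten rendered 48-h subjects for parameter
recovery, twenty seeded replicates for the cohort-level selection and
model-performance studies, 1,000 random epochs for the MAD oracle, 100
instances for the AUC oracle, and small-margin enumeration for the Fisher
oracle — sizes chosen so the whole suite completes in about a minute on one
core while keeping binomial uncertainty on the recovery rates small.
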