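# frailsense

Sensor analytics for identifying **pre-frailty** in community-dwelling older
adults from a single chest-worn (pendant) accelerometer.

Frailty is a geriatric syndrome of reduced physiological reserve; its
intermediate stage, pre-frailty (1–2 Fried criteria), is potentially
reversible, which makes its early, unobtrusive detection clinically valuable.
`frailsense` turns 48-h tri-axial chest acceleration recordings (50 Hz,
gravity units) into physical-activity-behavior, posture/stepping, and sleep
parameters, and discriminates pre-frail subjects from the pooled non-frail
and frail groups with cross-validated one-vs-rest decision-tree models.

## What it computes

**Activity intensity.** After a Daubechies wavelet low-pass at 12.5 Hz, each
6-s epoch (N = 300 samples) is summarized by the mean amplitude deviation of
the acceleration-vector norm rᵢ = √(xᵢ² + yᵢ² + zᵢ²):

```
MAD = (1/N) Σ |rᵢ − R̄|,   R̄ = (1/N) Σ rᵢ        (units: mg, 1 g = 1000 mg)
```

with cut-points MAD < 20 mg sedentary, 20 ≤ MAD < 90 light, MAD ≥ 90
moderate-to-vigorous (MtV).

**Wear validity.** Non-wear = runs of ≥ 90 min with no MAD, tolerating up to
2 interrupted minutes of MAD < 20 mg; a valid day has ≥ 8 h wear; parameters
are averaged over valid days and subjects with < 2 valid days are excluded.

**Posture and steps.** Steps are peaks of the wavelet band-passed
(0.5–3 Hz) vertical axis above 0.1 g; ≥ 3 consecutive steps with inter-step
gaps ≤ 2.5 s form a walking bout; non-walking time is lying (vertical
gravity component near zero) or upright, with sitting/standing resolved by a
transition-lean state machine anchored at walking and lying.

**Sleep.** The longest nocturnal (21:00–11:00) lying-dominated block is the
in-bed interval; a logistic rule on minute MAD, its rolling SD, and position
changes labels sleep/wake, from which TiB, SOL, TST, WASO, SE = 100·TST/(last
offset − first onset), and supine/prone/side shares are derived.

**Frailty modelling.** Fried criteria sum to non-frail (0), pre-frail (1–2),
frail (≥ 3). Feature selection is two-stage — filter (ANCOVA/LSD contrasts
p < 0.05 and Cohen's d ≥ 0.4 on both pre-frail contrasts), then embedded
(single-feature decision-tree one-vs-rest AUC > 0.7) — and four models
(stepping, activity-pattern, activity-behavior, combined) are evaluated with
stratified 5-fold cross validation (sensitivity, specificity, accuracy,
Mann–Whitney AUC; mean ± SD over folds).

A synthetic-data module generates everything the pipeline consumes: labeled
48-h signals with programmed step counts, postures, non-wear gaps, and sleep
structure, plus cohort feature tables calibrated to published group
means ± SDs (42 non-frail / 78 pre-frail / 33 frail).

## Worked example

Simulate a 48-h recording, run the pipeline on it, and cross-validate a
model on a calibrated cohort:

```sh
frailsense simulate --mode signal   --seed 5 --subject-id demo --out sim/
frailsense process  --recording sim/demo.csv --start-clock-s 72000 --out demo_features.csv
frailsense simulate --mode features --seed 5 --out cohort/
frailsense classify --features cohort/cohort.csv --model combined --seed 1 --out combined.json
```

The processed subject (`demo_features.csv`) contains, among its 30
parameters:

```
total_steps_k  walk_pct  total_sed_h  total_mtv_min  tib_min  tst_min  se_pct  hhs_met
         7.26      5.27         10.8          82.25    480.0    390.0   86.67      1.0
```

i.e. ~7,260 steps/day, 5.3 % of the day walking, 10.8 h sedentary, 480 min
in bed with 390 min asleep (86.7 % efficiency between sleep onset and
offset), and the MtV guideline (≥ 42 min/day) met — all consistent with the
generator's programmed schedule (8,000 steps on full days, TiB 480 / SOL 20 /
WASO 60 min). The classify step prints the cross-validated report, e.g.

```
combined: AUC 0.622 +- 0.017 -> combined.json
```

On Gaussian-calibrated cohorts the discrimination is substantially weaker
than on real recordings, because the sampler reproduces only the published
per-group means/SDs, not the joint structure of real behavior (see
`docs/methods.md`).

The per-column data dictionary (name, description, units, block) is
programmatic: `frailsense.features.FEATURE_DICTIONARY`.

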