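# Methods

## The scoring procedure

A cohort enters as one row per patient-day of tracker summaries. Eleven
channels are modelled: minimum and maximum daily heart rate (bpm),
overall stress level (a heart-rate-variability-derived index on
0–100), minutes per day in high stress and at rest, daily steps and
walking distance (km), and four sleep-phase durations (deep, light,
awake, total, minutes). The device's stress algorithm is proprietary;
stress values are treated purely as input data.

**Weekly reduction.** Each patient's first and last monitoring day are
dropped by ordinal position (the device is fitted and removed mid-day,
so both are incomplete); remaining days are averaged per channel,
ignoring nulls within retained days rather than imputing them — an
average is descriptive and imputation would smuggle in model
assumptions. Patients with fewer than `min_days` retained days
(default 3; one week of wear yields 7) are excluded and reported.

**Threshold derivation.** For each of the three scored categories
(walking → steps, heart rate → maximum heart rate, stress → overall
stress level; the map is configurable), the cutoff maximises the
Youden index J = sensitivity + specificity − 1 against the binary
mortality outcome. Candidate cutoffs are the midpoints between
consecutive distinct observed values plus ±∞ sentinels, so a cutoff
never coincides with an observation on continuous data. The scan
compares J through its integer numerator (TP·n₀ + TN·n₁), making ties
exact rather than floating-point accidents; ties are broken in favour
of higher sensitivity (a frailty screen should not miss cases), then
the smaller cutoff. Classification at a threshold is strict: a
positive-direction category calls the event when value > cutoff, a
negative-direction one when value < cutoff, and a value exactly at the
cutoff never scores.

**Scoring.** One point per breached category; the 0–3 total maps to no
/ mild / moderate / severe frailty ("borderline" is accepted as an
input alias for mild), and the binary frailty definition is moderate
or severe. Each category's default direction is its known association
with mortality: higher maximum/minimum heart rate, stress level and
high-stress minutes are adverse; more resting minutes, steps and
distance are protective.

**Discrimination.** AUCs are rank-based (Mann–Whitney identity,
midrank tie handling), which equals the trapezoidal area under the
empirical ROC curve exactly. The default confidence interval is the
Hanley–McNeil large-sample standard error with a normal approximation,
clipped to [0, 1]; the original study does not state its CI method, so
a reproducible closed form was preferred, with the DeLong
structural-components estimator available via `ci_method="delong"`.
Composite instruments enter comparisons as ordinal stage codes (FIFA
0–3, EFS-C 0–4, gait category 0–3 ordered by increasing frailty), not
as binary flags — the published AUC magnitudes are only attainable
with multi-level predictors at n = 50.

**Comparators.** The Edmonton Frail Scale bands are 0–5 not frail, 6–7
vulnerable, 8–9 mild, 10–11 moderate and ≥12 severe; 12 is classed
severe so that the 0–17 domain is partitioned without a gap. Gait
speed is distance walked in the 6-minute test divided by 360 s:
very slow < 0.5 m/s, slow 0.5–0.83 m/s (closed at 0.83, consistent
with the frail definition "speed below 0.83 or infeasible"), normal
above 0.83; an infeasible test is its own, frail, category. Raw EFS
points can be screened directly via `auc_rank` when the category
granularity is in doubt.

## The synthetic cohort generator

Real tracker data of this kind are not publicly available, so the
generator emulates their statistical structure. Each patient carries a
single latent frailty factor f ~ N(0, 1) — the minimal structure under
which a composite of several channels is meaningful. A channel's
patient-level mean is baseline + loading·f; daily values add iid
Gaussian noise and are clipped to physical ranges (clipping after
noise slightly attenuates extreme loadings but keeps the construction
simple). The heart-rate pair is built jointly (per-day min/max
ordering), stress minutes are rescaled if a day exceeds 1440 min, and
total sleep is the sum of its components, so every emitted record
satisfies the data-model invariants. Missingness is MCAR per cell at
`missing_rate` (default 0.02 — near-continuous wear).

Defaults define the emulated study conditions: 50 patients, 9
monitoring days (7 retained), baseline death logit −2.75 (6% mortality
at median frailty, the published overall rate), frailty effect 2.
Channel baselines are plausible elderly-cohort values (4000 steps/day,
max HR 110 bpm, overall stress 35, 60 high-stress and 600 resting
minutes); loadings put the mortality signal predominantly in the
stress and heart-rate channels, weakly in walking and not at all in
sleep, mirroring the direction and ordering of the single-parameter
AUCs the score construction presumes. None of the tests depend on the
specific baselines, only on loadings and effects. The generator
returns the latent table (f, true death probability), whose Bayes-
optimal predictor bounds any channel's achievable AUC and serves as a
test oracle. Not emulated: circadian structure, informative
missingness, competing risks, device error.

## Simulation studies and their problem sizes

* **Null calibration** — 200 replicates, n = 50, frailty effect 0.
  Thresholds fitted on one null cohort are evaluated on an independent
  null cohort; the held-out mean FIFA AUC should sit within 3 standard
  errors of 0.5. Held-out evaluation is essential: thresholds chosen
  by in-sample Youden maximisation are optimistically biased (mean
  in-sample null AUC ≈ 0.75 at these sizes), which is a property of
  retrospective cutpoint selection, not an implementation artifact.
  Replicates in which either cohort has no deaths are skipped, as the
  AUC is undefined there.
* **Planted-effect recovery** — 200 replicates, n = 2000, the entire
  signal planted in overall stress (loading 9) with a token walking
  effect. The derived stress cutoff should fall between the survivors'
  and non-survivors' mean weekly stress (the discriminating region),
  and the composite score should out-discriminate every unloaded
  channel, each in ≥90% of replicates.
* **Oracle agreement** — 500 random tied instances (n ≤ 60): the rank
  AUC against exhaustive case-control pair enumeration (agreement to
  1e-12) and the Youden scan against an exhaustive J-evaluation at
  every candidate cutoff.

## Numerical choices and degenerate inputs

Midrank AUC via `scipy.stats.rankdata`; a constant predictor yields
AUC exactly 0.5 with a `degenerate` flag and J = 0. A cohort without
both deaths and survivors raises an undefined-AUC error rather than
returning a number. CSV floats are read with round-trip precision so
write→read is the identity. Records with day gaps are handled
positionally; `day_index` is 0-based.

## Known limitations

Thresholds and their J/sensitivity/specificity are in-sample
quantities; at n ≈ 50 with very few events they are optimistic, and
any application to a new cohort should use `FifaResults.predict`
rather than refitting. The Hanley–McNeil interval undercovers for
AUCs near 1 at small n. The generator's single-factor structure cannot
probe multi-dimensional frailty, and passing simulation studies shows
correctness of the pipeline under the stated assumptions, not clinical
validity of the score. The choice of the walking category's operative
parameter (steps vs distance) is under-determined at these sample
sizes — both are screened, and the category map is a model argument
for exactly that reason.
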