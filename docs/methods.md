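# Methods

This note documents the scientific and numerical choices behind `circact`:
what each stage computes, the conventions it fixes where the underlying
definitions are ambiguous, what the synthetic cohort generator does and does
not emulate, and the known limitations.

## Data model and conventions

Actigraphy is represented as a dense 1-minute epoch grid from the recording
start: gaps never appear as missing rows, only as epochs flagged EXCLUDED
(non-wear) or as epochs outside the recorded span. Timestamps are naive
local wall-clock; a daylight-saving transition is simply a 23- or 25-hour
calendar day, and every hour-of-day label downstream comes from wall-clock
time, matching how wake times are reported clinically. Days are calendar
days, midnight-to-midnight, half-open.

## Wear-time quality control

Two nested filters with strict boundary semantics:

* a **day** is analyzable unless *more than* 360 minutes are missing
  (EXCLUDED plus unrecorded); exactly 360 keeps the day;
* a **participant** is retained only if a sleep diary exists and *not more
  than* 30% of the first 30 recorded days are invalid; exactly 30% retains.

Recordings shorter than 30 days are gated on all recorded days; recordings
shorter than one day fail with a distinct reason code. "First 30 days"
means the first 30 calendar days overlapped by the recording (the grid is
dense, so recorded and elapsed days coincide). Analyzable data are also
truncated at the first 30 recorded days, the same horizon the gate
inspects. Filters are idempotent and monotone: adding missingness can only
remove, never add, analyzable data.

## Circadian statistics

IS and IV are computed per (participant, week, setting) group; M10/L5/RA
per valid day.

* **IS** uses hour-of-day means pooled over all valid epochs sharing the
  wall-clock hour (epoch-weighted, not a mean of daily means), divided by
  the sample variance of the valid 1-minute epochs. Sample variances
  (`N−1`, `p−1` with `p = 24`) are used throughout, so complete periodic
  data gives IS = (N−1)p/((p−1)N) ≈ 1.0434, not 1.
* **IV** is the normalized lag-1 squared difference of the chronological
  per-hour means, with the sample variance of those hourly means in the
  denominator. Hours with fewer than 30 valid minutes are absent; lag-1
  pairs spanning an absent hour (or a calendar gap between group days) are
  skipped while the `N_h − 1` divisors keep the group's populated hour
  count. The minute-level denominator variant was considered and rejected
  as the default: the hourly-mean denominator is the convention of the
  standard nonparametric actigraphy toolchain and matches an hourly-computed
  IV; with 1-minute counts the minute-level variant deflates IV by roughly
  the ratio of within-hour to between-hour variance and would not be
  comparable across devices.
* **Degenerate cases** propagate as NaN, never zero — except IV on
  perfectly constant hourly means, which is 0 by definition (no
  hour-to-hour fragmentation exists; numerator and denominator both
  vanish).
* **M10/L5** rank the 24 hourly activity totals; partial hours (30–59
  valid minutes) are rescaled to a 60-minute equivalent so ranks are not
  biased downward, hours under 30 valid minutes are not computable, and a
  day needs at least 15 computable hours. RA is the difference M10 − L5
  (not the normalized ratio), so its units are activity counts.

## Wake-time detection

Wake time is the first rest→active transition ending the day's principal
rest period, detected deterministically in three stages:

1. **rank filtering** — centered median filters at a fine (121 min) and a
   coarse (241 min) width; non-wear epochs are forward-filled first;
2. **adaptive thresholding** — within a 24-h detection window (18:00 of the
   previous day to 18:00 of the target day), threshold =
   `q10 + 0.25 (q90 − q10)` of the smoothed distribution. Being built from
   quantiles, the rule is invariant to rescaling the counts; sitting at 25%
   of the rest–active contrast makes it insensitive to hour-scale
   fluctuations of active-period intensity while staying far above the
   near-zero rest level. Windows whose relative contrast
   `(q90 − q10)/q90` falls below 0.3 have no detectable rest period;
3. **morphological cleaning and coarse-to-fine localization** — active
   bursts shorter than 60 min are folded into rest; the principal rest
   period is the longest coarse-scale rest run (≥ 120 min) ending during
   the target day, and the reported wake edge is the nearest fine-scale
   rest→active transition within 120 min of the coarse edge.

The two-scale design is what makes the estimate robust on fragmented
records: the coarse filter erases rest/active bouts shorter than about half
its width, so brief awakenings and morning sedentary spells can neither
split the night nor masquerade as its end, while the fine filter preserves
minute-scale edge position. On noiseless square-wave profiles the detector
is exact, and it is equivariant under time shifts. Defaults (widths 121/241,
minimum rest run 120 min, threshold fraction 0.25) were fixed by validating
on synthetic two-state days: with a 61-minute single-scale filter,
fragmentation splits the nocturnal rest run often enough to bias detected
wake ~20 min early on heavily fragmented records, which would contaminate
condition contrasts; the defaults reduce that differential bias below ~2
minutes at the generator's operating point.

## Relapse assignment and windowing

Relapse is diary-defined: the first outpatient day (day k is
`discharge + k − 1`, k = 1..28) with any drinks. Missing diary days count
as missing, not as zero drinks — a participant whose diary ends early can
still relapse later than the diary shows, and the conservative choice is to
not fabricate abstinent days. Heavy-drinking days use ≥4 drinks for women
and ≥5 for men; when sex was not reported the lower (more sensitive)
threshold applies. Weeks count backward in 7-day blocks from the relapse
day (relapsers: week 1 is the 7 days before relapse; the relapse day opens
week 0 and the post-relapse phase) or from the day after the last recorded
day (non-relapsers: week 1 is the final 7 days). A leading partial week
simply takes the next index with its actual day count; any week-setting
group needs ≥4 valid days to produce weekly statistics, while daily metrics
keep every valid day.

The discharge analysis uses its own two groups per qualifying participant
(≥4 valid inpatient days): all valid inpatient days as the one valid
inpatient week, and the valid days of the first outpatient week. This is
deliberate: backward week indexing is anchored on relapse/recording end and
would split the short inpatient block across arbitrary week boundaries,
discarding most of the very data the pre/post-discharge contrast needs.
Post-relapse days are excluded from the discharge windows (weekly and
daily): with relapse occurring at a median of outpatient day 11, early
relapsers otherwise place post-relapse days — which carry the separate
relapse effect — inside the first outpatient week, confounding the
discharge contrast with the relapse contrast.

## Inference

* **Discharge** — `value ~ outpatient` + participant random intercept
  (REML, `statsmodels` MixedLM), Wald tests. Responses are standardized
  internally before fitting and the estimates mapped back, purely for
  numerical conditioning (the circadian variables span five orders of
  magnitude); optimizer fallbacks (lbfgs → powell → cg) handle the
  occasional singular iteration. Reported degrees of freedom are residual:
  observations − participants − fixed-effect columns. 95% CIs are
  β ± 1.96 SE.
* **Relapse probability** — the binary outcome is constant within
  participant, which makes the subject-specific logistic random-intercept
  likelihood unidentified: the intercept variance diverges and Wald SEs
  become arbitrarily large (fits of this model with standard mixed-model
  software show exactly that signature — huge SEs and near-zero power),
  while variational approximations err in the opposite direction. The
  package therefore estimates the marginal logistic model by GEE with an
  **independence** working correlation, the Mancl–DeRouen bias-reduced
  sandwich covariance, and a t reference on participants − 2 degrees of
  freedom (the plain sandwich with a normal reference is measurably
  anti-conservative at ~100 clusters).
  Independence matters: relapsers contribute systematically fewer
  (pre-relapse) rows than non-relapsers, and under such informative cluster
  sizes an exchangeable working correlation — whose estimate degenerates
  toward 1 here — is badly anti-conservative (measured null rejection
  ~0.13–0.25 vs ~0.05 for independence). Odds ratios are exp(β) per unit
  of the circadian variable; wake time enters in hours for this family.
  The literal random-intercept model remains available
  (`engine="glmm_vb"`) but its z-statistics are not calibrated.
* **Relapse effect** — `value ~ post_relapse + outpatient` + random
  intercept; the post-relapse coefficient is reported.
* **Group comparisons** — each participant contributes their study-period
  mean per variable; two-tailed t-tests and the absolute pooled-SD
  standardized mean difference (Cohen's d with unequal-n pooling). Wake
  means are also rendered as HH:MM.
* **Assumption checks** — residual-vs-fitted correlations (location and
  spread) and the normal Q–Q correlation of ordered residuals, with a flag
  below 0.98.

A note on interpretation: because relapsers' pre-relapse span contains
proportionally more inpatient time, any variable shifted by discharge (IV
in particular) acquires a composition-driven association with relapse in
the probability models even when none is programmed. This is a property of
the windowing design itself, visible in the worked example, and worth
keeping in mind when reading such coefficients.

## Synthetic cohort generator

The generator's defaults are the study conditions: 103 participants, 28
outpatient days, relapse fraction 26/103 with relapse day ~ normal(10.5,
6.09) truncated to [1, 28] (median ≈ 11), inpatient wear 0–7 days with
median 2 and ~35% reaching the ≥4-day discharge subset, so a default cohort
yields a subset of ≈36.

Each participant follows a two-state diurnal process. The schedule is a
habitual wake time (participant mean 06:00 ± 45 min between persons, ± 30
min day-to-day jitter — the jitter is what erodes IS) with a 9-h sleep
span; both wake and bed derive from the **same day's** condition, as when a
clinic enforces lights-out until the discharge day. The early operating
point (wake 06:00, bed ≈ 21:00) is deliberate: it keeps bedtimes before
midnight in every condition, so programmed wake shifts never push activity
across the day boundary, where it would silently alter the weekly
statistics of adjacent groups. Counts are negative binomial while active
(mean 5/min, dispersion 4; participant-level lognormal activity scale) and
sparse Poisson while at rest (0.2/min), giving hourly totals ~300 and L5
~10 on the scale typical of wrist actigraphy. Non-wear runs arrive at
0.05/day with ~90-min mean length and are flagged EXCLUDED.

Fragmentation has two layers:

* **state-flip bouts** — sedentary spells (exponential length, mean 45
  min, capped at 120 min) suppressing activity inside the active span at a
  fixed 0.75/day. The cap and the active-span restriction are deliberate:
  unrestricted two-sided flips produced sustained nocturnal activity runs
  and multi-hour "naps" that made the programmed wake time generatively
  meaningless on a nontrivial fraction of days. Realized IV rises
  monotonically with the bout rate (this is the generator's fragmentation
  dial);
* **hourly activity modulation** — mean-preserving lognormal factors per
  clock hour on the active-period mean. Hour-to-hour amplitude variance is
  precisely what IV measures, so this is the lever used to *set* IV per
  condition without touching the rest–activity state structure that wake
  detection and M10/L5 ranking depend on.

Because weekly IV is a nonlinear functional of these processes, programmed
IV levels are reached by **calibration**: the generator estimates the
modulation-SD → expected-weekly-IV map by Monte Carlo under a fixed
internal seed, forces it monotone, inverts it per condition
(PCHIP + Brent), and polishes the operating point with one Newton step at a
larger replicate budget. Common random numbers — profile, bouts and the
standard-normal field behind the modulation are shared across grid points
and conditions — make the Monte-Carlo error largely cancel in differences,
which is what matters for programmed *deltas*. Calibration replicates score
the interior 7 days of 9-day simulations so edge days carry the same
structure as weeks inside a longer recording; the inpatient condition is
instead scored on standalone leading blocks of 4–7 days, the exact shape of
its one valid week. The calibrated map is cached per spec.

Programmed condition effects (defaults): discharge shifts wake +3,461 s,
multiplies active/rest means by 1.12/0.75 (raising M10, lowering L5), and
lowers expected weekly IV by 0.214 from its inpatient level; relapse shifts
wake a further +3,190 s and lowers expected IV by another 0.08. The
baseline outpatient IV operating point is 0.43, chosen so all three
condition targets (0.644 / 0.43 / 0.35) sit inside the feasible IV range of
the two-state profile (floor ≈ 0.33 at the default noise settings);
observed outpatient IV in comparable cohorts (~0.39) anchors the
plausibility of that neighborhood. Diaries mirror the schedule with 15-min
reporting noise, relapsers' diaries start recording drinks on the
programmed relapse day, and the truth table records every programmed
parameter per participant.

`figure1_preset` builds the 126-participant wear-time fixture
deterministically: 5 participants lose their diaries and 18 receive 7-hour
non-wear runs on 11 of their first 30 days, so the cleaning cascade retains
exactly 103 and the exclusion report names all 23.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no seasonal or weekday structure, no light or
posture channels, no diary–actigraphy discordance beyond independent
reporting noise (real studies reconcile these manually), no gradual
post-discharge drift (effects switch on discharge/relapse day), no
autocorrelated minute-to-minute counts within a state, and relapse severity
is binary — an isolated lapse and sustained heavy drinking are the same
event. Parameter recovery on these cohorts validates the *pipeline's*
correctness, not the clinical effect sizes themselves.

## Validation summary

The test suite checks, among others: exact closed forms (periodic-week IS,
alternating-hour IV), equality with naive double-loop oracles at 1e-10,
byte-identical write→read round trips, the 126→103 cohort flow with all 23
exclusions named, wake MAE well under 30 min on noisy two-state days (exact
on noiseless ones), recovery of all four programmed discharge/relapse
coefficients within 2 SE in ≥90% of 100 simulated cohorts, null rejection
rates of the discharge LMM and relapse logistic model inside [0.02, 0.09],
and monotone response of realized IS/IV to the jitter and fragmentation
dials. Simulation sizes in the tests (100 recovery cohorts, 250 null
cohorts, 20–50-week calibration probes) were chosen to keep Monte-Carlo
error comfortably below the tolerances they guard while the whole suite
stays conveniently runnable on a single CPU.

## Known limitations

* The 30-day truncation means late-outpatient data of participants with a
  full 7-day inpatient week are unused.
* IV under missingness: skipped lag-1 pairs with `N_h − 1` divisors
  slightly deflate IV on gappy weeks; with the default day-validity rules
  the effect is well under the statistic's sampling noise.
* The wake detector reports one wake per day and no sleep-onset or
  efficiency measures; napping behavior outside the principal rest period
  is invisible to it by design.
* The epoch grid is strictly 60-second and continuous in naive local time;
  a real export recorded across a daylight-saving transition would show a
  timestamp jump and is rejected by the reader rather than re-aligned.
  Hour-of-day labels are wall-clock throughout, which is the convention the
  reported wake times assume.
* The discharge contrast absorbs whatever the first outpatient week
  contains — including early relapses — exactly as a model with no relapse
  term must.
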