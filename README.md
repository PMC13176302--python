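# circact

Nonparametric circadian rest–activity analysis of wrist-actigraphy cohorts
followed from inpatient alcohol-use-disorder treatment into the outpatient
period, with relapse-aligned longitudinal modelling.

People discharged from structured inpatient treatment lose the clinic's
fixed schedule, and disruption of the rest–activity rhythm is a candidate
marker (and possible driver) of return to drinking. This package implements
the full analysis chain such a study needs, end to end and testable without
any clinical data:

1. **I/O** — Actiware-style 1-minute epoch exports (timestamp, activity
   count, EXCLUDED non-wear flag), daily sleep/alcohol diaries, and a
   participant manifest (`circact.io`);
2. **Wear-time QC** — days missing more than 6 h of epochs are dropped, and
   participants are excluded when no diary exists or when more than 30% of
   the first 30 recorded days are invalid (`circact.qc`);
3. **Circadian statistics** — weekly interdaily stability and intradaily
   variability, daily M10 / L5 / RA (`circact.metrics`);
4. **Wake-time detection** — a deterministic coarse-to-fine activity-onset
   detector (rank filtering, adaptive quantile thresholding, morphological
   cleaning of the rest/active profile) (`circact.wake`);
5. **Relapse-aligned windowing** — diary-based relapse assignment (any
   drinking day during the 28-day outpatient follow-up; heavy-drinking days
   at ≥4 drinks for women, ≥5 for men), backward week indexing from the
   relapse day or recording end, and inpatient/outpatient, pre/post labels
   (`circact.windows`);
6. **Inference** — three random-intercept model families (effect of
   discharge, probability of relapse, effect of relapse) plus group
   comparisons with standardized mean differences (`circact.models`);
7. **Synthetic cohorts** — a calibrated generator that emulates all of the
   above inputs with programmed effect sizes, so every stage is validated
   by parameter recovery (`circact.simulate`).

## The statistics at the core

With `X_i` the valid 1-minute activity counts of a (participant, week,
setting) group, `X̄_h` the `p = 24` hour-of-day means, `X̄` the overall mean,
and `X̄_j` the chronological per-hour means (`N_h` of them, mean `m`):

    IS = [ Σ_h (X̄_h − X̄)² / (p−1) ] / [ Σ_i (X_i − X̄)² / (N−1) ]

    IV = [ Σ_j (X̄_j − X̄_{j−1})² / (N_h−1) ] / [ Σ_j (X̄_j − m)² / (N_h−1) ]

Both use sample (not population) variances, so a perfectly daily-periodic
week yields IS = (N−1)p/((p−1)N) ≈ 1.04337 rather than 1. Daily M10 and L5
are the means of the ten largest and five smallest of the 24 ranked hourly
activity totals; RA is the plain difference M10 − L5. Wake time is the end
of the day's principal rest period, in seconds from midnight.

The models are `value ~ outpatient`, `relapsed ~ value` and
`value ~ post_relapse + outpatient`, each accounting for repeated
measurements within participants (random intercepts for the linear models;
cluster-robust marginal inference for the logistic one — see
`docs/methods.md` for why).

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/04_discharge_models.py
```

The second script prints the cleaning cascade of the constructed
126-participant fixture:

    cohort flow: 126 in -> 5 without diary, 18 failing wear time -> 103 retained

and the third fits the discharge models on the 39-participant inpatient
subset of the main simulated cohort (programmed effects: wake +3,461 s,
IV −0.214):

     variable      beta       se  df  statistic  p_value    ci_low   ci_high
           IV   -0.1919   0.0147  35   -13.0596      0.0   -0.2207   -0.1631
    wake_time 3434.5078 205.8340 422    16.6858      0.0 3031.0733 3837.9423

i.e. after discharge the fitted wake time is about 57 minutes later and the
fitted hourly fragmentation (IV) about 0.19 units lower than inpatient, both
within two standard errors of the programmed truth. The same cohort can be
driven through every stage at once:

```bash
circact run --seed 1 --n 103 --out results/full_run
```

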