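# Methods

## The partitioning model

The framework treats spring budburst as the crossing of a species-specific
forcing threshold: degree days above a base temperature accumulated from
Julian day 1. Under a null hypothesis that warming changes nothing but
spring temperatures, the baseline budburst day `O_Ci` fixes the species'
threshold (the baseline degree-day sum at `O_Ci`), and the expected
budburst day under the warmer climate is wherever that same sum is banked.
Four quantities follow per record:

| quantity | definition | units |
| --- | --- | --- |
| forcing change `F_C` | warmer minus baseline degree days over days 1..`O_Ci` | degree days |
| expected response `N_E` | day shift minimizing the absolute forcing mismatch | days |
| budburst temperature `T_B` | `F_C / N_E` | °C (degree days per day) |
| phenological lag `N_C` | `N_E − N_O` | days |

The lag deliberately aggregates every non-forcing constraint — chilling
deficit, photoperiod limitation, moisture or frost stress — into one number
with a sign convention (positive = constraints tightened). It requires no
species-specific chilling or photoperiod model, which is the point: those
are rarely available consistently across a synthesis. The flip side is that
a lag by itself does not identify *which* constraint moved; that needs
on-site covariates outside this package's scope.

### Numerical conventions

- **Degree days** accumulate `max(T − base, 0)` of daily means; base
  temperature defaults to 0 °C and is a parameter for sensitivity checks.
  Accumulation always starts at day-of-year 1.
- **The day search is over integer days** (the defining sums index whole
  days). Candidate shifts keep the expected day inside the warmer series'
  coverage, so both advances and delays are representable. Ties on the
  absolute mismatch prefer the smaller `|n|`, then the positive (advancing)
  `n` — the most conservative reading. An optional `mode="linear"` refines
  the crossing sub-daily by interpolating the cumulative forcing across the
  crossing day; the integer mode is the default and is what all reported
  numbers use.
- **`N_E = 0` leaves `T_B` undefined** (0/0). It is carried as NaN with an
  explicit flag and excluded from group means, never imputed.
- **Unreachable thresholds** (the warmer series never banks the baseline
  sum) raise a diagnostic error stating the attainable forcing range rather
  than returning a boundary value.
- **Spring warming** is the mean daily temperature difference over Julian
  days 1–182; both series must cover that window.
- **Calendars**: 1-based day-of-year as given; multi-year climates are
  averaged day-by-day into one representative series per regime before
  partitioning. Temperature gaps of ≤ 5 days are linearly interpolated at
  ingestion (with a logged note); longer gaps are rejected.
- Human-readable outputs round to one decimal day / °C; machine outputs
  keep full precision (the partition CSV round-trips bit-exactly).

### Record selection rules

Ingestion enforces the schema's selection rules: budburst before Julian
day 213, boreal/temperate consistency with mean annual temperature
(boreal = MAT < 6 °C), and the identity `N_O = O_Ci − O_Wi` when both the
observed warm budburst day and the response are given. Violations are
reported per row, never silently dropped.

## Synthetic climates

The generator exists so the whole pipeline can be validated against known
ground truth without any external data. One climate is

```
temp_d = MAT − amplitude · cos(2π (d − coldest_day)/365) + e_d
```

with `e_d` a stationary AR(1) anomaly. Defaults: seasonal amplitude 12 °C,
noise SD 2 °C, lag-1 autocorrelation 0.7 (roughly the persistence of daily
mid-latitude weather), coldest day 15 (northern-hemisphere mid-January).
The warming treatment adds `offset · weight(d)` where the weights are
normalized so the spring-window mean change equals the nominal offset for
every profile: `uniform` warms all days equally; `winter_biased` puts the
whole offset on sub-zero days (raising mean temperature while adding almost
no spring forcing — the mechanism behind smaller forcing changes at equal
spring warming in cold regions) and degenerates to uniform when no sub-zero
days exist; `spring_biased` concentrates it on above-zero days after the
seasonal minimum.

Budburst is simulated as the first day the cumulative forcing reaches the
species threshold; an injected lag is then added to the warmer-climate
date only. The lag is purely additive and mechanism-free, matching the
aggregate-lag philosophy of the statistic it is meant to exercise.
The default study design (`study_config`) spans MAT 2–12 °C (both climatic
regions), warming offsets 1–3 °C, forcing thresholds 150–450 degree days
and injected lags {0, 2, 5, 10} days — the envelope of the observational
and experimental contrasts the method targets. Replicates whose baseline
budburst would fall after day 213 are redrawn, mirroring the spring-event
selection rule.

What the generator does **not** emulate: spatial correlation between
locations, trends within a record's observation period, measurement error
in reported budburst dates, and any mechanistic chilling/photoperiod
response. Passing recovery tests therefore show the arithmetic and the
statistics are right, not that real records meet the threshold-crossing
assumptions.

## Statistical layer

- **Group summaries** are arithmetic means per factor level (budburst
  event × approach/origin/region/growth form), computed only over records
  where the variable is defined.
- **Group contrasts** fit `response ~ factor` per factor and event with a
  random location intercept and a species variance component (statsmodels
  `MixedLM`; REML for reported standard errors). When the random structure
  is unidentifiable — no replication within locations or species — or the
  fit fails to converge, the model falls back to OLS with a logged note,
  and p-values switch from normal to t with the residual degrees of
  freedom. Least-square means come from the treatment-coded fixed effects;
  pairwise comparisons use unadjusted α = 0.05 and are displayed as compact
  letters (levels sharing a letter do not differ).
- **Stepwise selection** regresses the observed response on nine
  unstandardized candidates (altitude, latitude, MAT, MAP, spring
  phenology, budburst temperature, forcing change, spring warming,
  phenological lag) starting from the full model and applying the best
  single-term deletion or addition by AIC until stationary. Deletions
  accept exact AIC ties so a perfectly redundant (collinear) term is
  dropped; additions must strictly improve. Listwise deletion handles
  missing covariates and the dropped count is recorded.
- **Variable influence** is reported as single-term-deletion ΔAIC from the
  final model, normalized to 100% together with an intercept row that takes
  the remainder of the intercept-only ΔAIC not covered by single deletions
  (floored at zero). This is one defensible reading of an "AIC %"
  decomposition, documented as an interpretation — ΔAIC shares are not
  additive in general, so the shares are descriptive, not variance
  components.

Because the partition computes `N_C = N_E − N_O` identically, a regression
of `N_O` on `F_C`, `T_B` and `N_C` must put the `N_C` coefficient near −1
(the deviation reflects only the nonlinearity of `N_E` in `F_C/T_B` and
integer-day discretization); the recovery suite checks this at n = 500.

## Known limitations

- AIC-based stepwise selection retains any pure-noise predictor with
  probability ≈ 0.16 (the chance its likelihood-ratio statistic exceeds 2),
  so with seven noise candidates about one run in twelve keeps three or
  more of them. The selection-recovery rate reported by the acceptance
  script sits around 0.90–0.95 accordingly; this is a property of AIC, not
  of the implementation.
- Integer-day search discretizes `N_E` to whole days; individual lags are
  recovered only to ±1 day (means are much tighter).
- The mixed model uses a variance-component approximation for crossed
  location × species random effects rather than a fully crossed design.

## Problem sizes

Tests and the acceptance script use 200-record recovery datasets
(365-day series), a 500-record set for the regression checks, 100 random
series pairs for oracle equivalence and 100 seeded runs of the
selection-recovery simulation — sizes at which every Monte-Carlo check is
stable under reseeding while the full suite stays fast on one core.
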