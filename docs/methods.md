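# Methods

This note records the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Catch accounting and CPUE

A weekly opening yields, per fin clip (AD = adipose-clipped, AI = intact),
counts of fish visually identified (VSI) as lower vs. upriver stock, plus
adult Chinook that were never identified: fish taken out of the net by sea
lions (recorded from 2021 on) and a few early-year unidentified fish.
Estimation is a two-stage proportional apportionment:

1. a sea-lion take is split into AD/AI by the week's sampled clip ratio,
   both stocks combined — the taken fish were lost before any examination,
   so the clip mix of the sampled catch is the only available basis;
2. within each clip, the no-VSI fish are assigned to stocks by the sampled
   VSI proportion of that clip, so per-clip totals are conserved exactly.

CPUE is the estimated total divided by the number of drifts.  The
clip-first order is not arbitrary: it is the order that reproduces the
fractional no-VSI AD/AI values printed in the source catch table (checked
cell by cell in the tests).  Degenerate cases are explicit errors rather
than silent zeros: a positive take with no sampled fish, or no-VSI fish in
a clip with no VSI'd fish of that clip, have no basis for apportionment.
Jack-sized fish (fork length ≤ 560 mm) are excluded at ingest; the
threshold is strict (`> 560` is adult).

Assumptions: fish lost to sea lions are a random draw from the catch with
respect to clip and stock, and drifts are exchangeable within a week (no
soak-time or gear-selectivity adjustment — fish per drift is the effort
unit).

## Stratification

Samples are pooled across weeks under three guidelines: the same strata for
both VSI stocks; at least 20 fish per VSI stock per stratum and at least 2
AI fish of each stock; as many strata as possible.  A greedy left-to-right
sweep closes a stratum as soon as the minima are met and folds a deficient
tail into the last complete stratum.  Because feasibility is monotone under
adding weeks, the greedy sweep attains the maximal number of strata; the
tests verify this against a brute-force enumeration of all contiguous
partitions on small instances.  A year that cannot meet the minima at all
becomes a single stratum flagged `deficient`, with a warning.  Dam-side
(adult-fish-facility) samples use the analogous rule with a ~100-fish
target per stratum; published pooled dam strata are accepted as-is when
supplied.

## Tag-rate-balanced composition (the balancing rule)

Within a stratum and a (VSI stock, clip) group, each fish contributes one
count keyed by origin category (H = clipped, HNC = AI with a PBT
assignment, W = AI unassigned), reporting group (PBT-informed when
assigned, observed GSI otherwise), and broodstock.  A broodstock `b` with
`n_b` assigned fish and tag rate `r_b` represents `n_b / r_b` hatchery fish;
the surplus `n_b (1/r_b - 1)` is subtracted from the PBT-unassigned fish
whose observed reporting group equals `b`'s expected one, proportionally
across broodstocks competing for the same pool.  This prevents untagged
hatchery siblings from being counted a second time as natural-origin fish.
When the pool is smaller than the total surplus, the subtraction clamps at
zero: the broodstocks receive only what the pool supplied (allocated
pro-rata), the residual surplus is discarded, and a warning records it.
Group totals are conserved in every case — balancing only moves counts
between cells — so reporting-group sums reproduce the abundance input to
machine precision.  The discarded-residual choice (rather than
redistributing to other reporting groups) is deliberate: the balancing rule
is defined within an observed reporting group, and inventing cross-group
flows would have no observational support.  Counts are normalised within
the group and multiplied by the group's abundance (summed weekly CPUE for
fishery strata, AD/AI dam counts for dam strata).

The implementation is vectorised over cells; the test suite pins it to an
independent one-fish-at-a-time enumeration for small strata, and checks
monotonicity (lowering a tag rate weakly raises that broodstock's estimate
and weakly lowers the matching natural-origin cell).

## Bootstrap intervals

Uncertainty in composition is estimated by resampling fish with replacement
within (stratum × VSI stock × fin clip) cells, re-running the full
estimator, and taking percentile intervals (default B = 1000, α = 0.10 →
90% intervals).  Abundance inputs are held fixed: the intervals express
composition uncertainty only, not CPUE sampling error.  Cells absent from a
replicate contribute zero, so rare cells get honestly wide, zero-anchored
intervals.  The generator is `numpy`'s PCG64 with a caller-supplied seed;
given the seed, intervals are reproducible.  On a known binomial cell the
percentile interval matches the closed-form binomial quantiles, and across
seeded replicates of a known composition the empirical coverage of the 90%
intervals is checked to lie in 85–95%.

## Concordance

A fish is concordant when the geographic side (lower/upriver of Bonneville)
of its genetic reporting group matches its visual call.  Reporting groups
whose run timing falls outside the spring management period still carry a
geographic side; such fish stay in the denominators and count as discordant
when on the wrong side, which is how the published subtotals are tallied.
The pooled percentage uses pooled numerators and denominators, so it always
lies between the per-stock percentages.  Zero denominators are reported as
missing, not zero.

## Travel time and lag selection

Weekly mean travel times pool PIT records across years and drop weeks with
fewer than 6 fish.  The migration rate is distance/days to one decimal; the
fishery-to-dam distance is a named constant (235 − 34 = 201 Rkm).  The
CPUE-to-dam lag is selected in whole statistical weeks, either as the
difference between the two series' *initial* peaks (first local maximum
exceeding half the series maximum — the run can shoulder before its highest
week) or as the candidate lag maximising regression R² with ties broken
toward the smaller lag.  Day-resolution lags are deliberately out of scope:
the dam counts are weekly, so a finer lag would be spurious precision.

## In-season regressions and forecast scoring

The regression is ordinary least squares *with an intercept* of the dam
count at week w + lag on CPUE at week w.  An intercept is required: the
published week-ahead predictions are inconsistent with a through-the-origin
line (slope × CPUE alone does not reproduce them), while the
intercept-bearing reconstruction does to within CPUE rounding.  Weeks
missing on either side of a pair are dropped, never imputed.  A constant
response is fitted as a flat line with R² = 0; fewer than two pairs, or
zero CPUE variance, are errors.

In-season, the fit is recomputed on nested prefixes of the paired data
starting at n = 3.  The convergence point is the smallest n whose slope,
and every later slope, lies within a relative tolerance (default 0.20) of
the final-season slope; 0.20 is the value that reproduces the published
five-point convergence on all four complete printed slope sequences, and it
is exposed as a parameter.  The final point alone cannot establish
convergence (it is trivially within tolerance of itself), so a sequence
with no earlier qualifying point reports no convergence.  From the
convergence point onward the current fit predicts up to three future weekly
counts from the next CPUE readings; predictions are not clamped at zero
(the published table prints small positive values where a clamp would have
printed 0).  The cumulative prediction is scored by
APE = |observed − predicted| / observed × 100 and averaged into MAPE.

The default in-season lag is fixed at 2 weeks (configurable), consistent
with peak-season travel of ~23 days: fish sampled on the opening day pass
the dam 14–20 days later, i.e. two statistical weeks after the opening.

## Synthetic scenarios

The generator emulates the structure the analysis assumes: a Gaussian
weekly run curve per stock (a bimodal option exists to stress the
initial-peak detector); weekly estuary cohorts thinned into Poisson drift
catches at a fixed catchability (expected CPUE per 1000 fish of the weekly
cohort, default 0.20 so peak CPUE lands in the observed few-per-drift
range); sea-lion removals (default rate 0.30) taken before identification;
per-fish clip, reporting group, broodstock and PBT-tag draws; VSI calls
flipped with stock-specific probabilities (defaults 0.114 upriver, 0.264
lower, matching the observed multi-year discordance); and dam arrivals
lagged by lognormal travel times whose weekly means fall linearly from 44
to 12.5 days over weeks 13–19.  Run-size defaults are the recent-decade
averages (150,485 upriver; 77,442 lower).  With zero travel noise the
week offset is exactly ⌊days/7⌋, making constructed-lag tests exact.  A
fixed seed reproduces the bundle byte-for-byte.

What passing recovery tests show: the pipeline is internally consistent —
composition, concordance, lag and slope estimates recover the generating
parameters at realistic sample sizes.  What they do not show: robustness to
features the generator omits — within-week run-timing differences between
stocks, year-to-year catchability drift, non-random sea-lion selection,
GSI misassignment between reporting groups (observed GenStock is generated
without error), and discharge-driven travel variation.  Conclusions about
real-data accuracy rest on the fixture-based checks, which cover exactly
the quantities the source study printed.

## Known limitations

* Full-season regression slopes and R² against dam counts require external
  weekly count series (the published dam table pools early weeks into
  strata); they are exercised on synthetic data only.
* Tag rates are consumed as data; their estimation from hatchery records is
  out of scope.
* The VSI error model is diagnostic only — composition estimates are not
  corrected for visual misclassification.
* Stratified-bootstrap intervals ignore uncertainty in the CPUE/dam
  abundance inputs.
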