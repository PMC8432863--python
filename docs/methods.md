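# Methods

`camtraptime` implements a temporal-interaction analysis for camera-trap
detection data: when during the 24-h day do species travel past cameras,
how much do their activity patterns overlap, and do detections of one
species cluster in time around detections of another at shared stations.
This note records the statistical models, the defaults and why they were
chosen, what the synthetic data generator does and does not emulate, and
the numerical conventions.

## Independent capture events

Raw camera-trap records oversample slow or lingering animals.  The analysis
unit is therefore the *capture event*: within each station x species chain,
a record is suppressed when it falls strictly less than 30 minutes (the
`window_minutes` default) after the last **retained** event of its chain.
This rolling rule keeps the earliest capture of every cluster and
guarantees retained events are at least the window apart; comparing to the
immediately preceding raw record instead would allow a chain of sub-window
records to suppress indefinitely while leaving retained events closer than
the window.  A record at exactly 30 minutes is retained ("at least 30
minutes apart" is the definition of independence here).  Records carrying
distinct individual ids form separate chains and never suppress one
another — distinguishable individuals are independent evidence of activity
— while records without an id are treated as indistinguishable.  Paired
cameras at one station are one detection stream keyed by `station_id`.
Clock times are used as-is; no sunrise/sunset standardization is applied
(appropriate for tropical dry-season data where day length barely moves).

## Diel activity as a circular density

Event times of day are angles t in [0, 2pi) (midnight = 0, noon = pi).  A
species' activity pattern is estimated by a von Mises kernel density

    f_hat(t) = (1/n) sum_i vM(t; mu = t_i, kappa = kappa_kernel),

evaluated on a 128-point uniform grid and renormalized so the
rectangle-rule integral on the circle is exactly 1 (the raw kernel mean
already integrates to 1 up to spectral quadrature error, which for a
128-point grid is far below the 2-decimal reporting precision of overlap
coefficients).  The smoothing concentration is the circular rule-of-thumb

    kappa_RT = [3 n kappa^2 I2(2 kappa) / (4 sqrt(pi) sinh^2(kappa))]^(2/5)

applied to the maximum-likelihood von Mises concentration of the sample
(solving A(kappa) = R-bar, A = I1/I0), times an `adjust` multiplier: 0.8
when the small-sample overlap estimator is in force, 1.0 otherwise — the
convention of the overlap-estimator simulation literature.  Both the rule
and the multiplier are configurable; nothing downstream assumes them.
Degenerate samples (all angles numerically identical) are rejected with
advice to jitter, since the ML concentration diverges.

Sampling from a fitted pattern — the *smoothed bootstrap* draw used by
interval estimation and by the randomization nulls — picks an observed
time uniformly and adds von Mises noise of the kernel concentration, which
is an exact draw from the kernel estimate.  Fitted patterns store their
sample sorted, so a pattern (and any resampling from it) is invariant to
input row order.

## Coefficient of overlapping

The overlap between two activity densities is Delta = integral of
min(f, g), in [0, 1].  Two estimators:

* **Dhat1** — rectangle-rule integral of min(f_hat, g_hat) on the shared
  grid; used when the smaller sample has fewer than 75 events.
* **Dhat4** — 0.5 [ mean_i min(1, g_hat(x_i)/f_hat(x_i)) +
  mean_j min(1, f_hat(y_j)/g_hat(y_j)) ] over the observed times; used at
  75 events and above.

The 75-event switch and the rule that a pair is skipped unless both
samples exceed 30 events follow the established simulation guidance for
these estimators.  Estimates are clipped to [0, 1]; Dhat1 is exactly
symmetric, Dhat4 symmetric to float precision.

### Confidence intervals

95% intervals come from the smoothed bootstrap (default 10,000 resamples;
analyses in this repository use 1,000–2,000 where runtime matters, stated
per script): resample pairs are drawn from each sample's fitted kernel and
the estimator is recomputed per pair.  The default interval takes the
bootstrap quantile deviations **about the bootstrap mean** and recentres
them on the point estimate.  The reason is specific to smoothed
resampling: bootstrap replicates estimate the overlap of the *kernel
densities*, which differs from the point estimate by an extra round of
smoothing, so the classical basic interval (which subtracts the
bootstrap-vs-estimate shift once more) removes that shift twice and
undercovers.  In a calibration study over random von Mises pairs
(n = 100 per group, 1,000 resamples, 100 replicates) measured coverage was
81% for the basic interval, 54% for percentile, 93% for the recentred
quantile interval and 94% for a normal interval with bootstrap sd; the
recentred quantile form is the default, with `basic`, `perc` and `norm0`
available via `ci_method`.  When a bound leaves [0, 1] the same interval
is recomputed on the logit scale of the bootstrap values and
back-transformed; final bounds are always clipped to [0, 1].  An interval
need not contain the point estimate by construction, but low <= high in
[0, 1] always holds.

## Equality of activity patterns

Whether two samples share an activity distribution is tested by
randomization: the observed statistic is the overlap between the two
fitted kernels (estimator per the sample-size rule); the null fits a
kernel to the pooled sample and draws R (default 999) smoothed sample
pairs of the original sizes, recomputing the statistic each time.  Small
overlap is the only evidence of difference, so the rejection region is
one-sided low and p = (#{null <= observed} + 1)/(R + 1) — the add-one rule
keeps p positive and the test exact-level.  Reported tiers are `p<.001`,
`p<.05`, `ns`.  Measured calibration: type-I rate 0.035 over 200 null
pairs (n = 75, R = 199) at alpha = 0.05; power ~1.0 against fully
separated (antipodal, kappa = 4) alternatives at n = 100.  No
multiple-testing correction is applied across a table of pairwise
comparisons; tiers are reported raw.

## Temporal spacing (spatiotemporal avoidance/attraction)

For an ordered pair (A, B) at every station where both occur: for each A
capture and each direction independently, the offset to the nearest B
capture in that direction is recorded iff no other A capture lies strictly
between (otherwise that reference is excluded *in that direction* — the
per-direction reading uses maximal data and is applied identically to
observed and null data, so the test stays valid) and the offset is within
the 12-h window.  A simultaneous B capture counts as an "after" offset of
zero.  Offsets aggregate into upper-closed hourly bins -12..-1, +1..+12
(bin +k covers ((k-1)w, kw]; a 30-minute variant uses w = 0.5 with 48
bins); each bin count divides by the number of A references *retained* in
that direction (references retained but with no B inside the window stay
in the denominator).

The null randomizes B 1000 times: per station the B capture count is
preserved, each randomized detection gets a uniformly random whole day
within that station's deployment window and a time of day drawn from B's
activity kernel fitted to all B events pooled across stations.  This
preserves where, how much, and at what time of day B is detected while
destroying any day-level or finer association with A; A events are never
moved.  The entire offset/binning procedure — including exclusions and
denominators — is re-run on every randomized dataset.

Per bin, the two-sided permutation p doubles the smaller add-one tail
count, capped at 1; Bonferroni multiplies by the number of bins of the one
pair analysis (24 at defaults).  A direction flag marks whether the
observed probability sits above or below the null median.  Discreteness
constraint worth knowing: the smallest achievable raw p is 2/(R + 1), so
with 24 bins an adjusted p below 0.05 requires R >= 959 — Bonferroni
significance is simply unreachable with substantially fewer
randomizations, which is one reason the method's default is R = 1000.
Under double randomization (B re-randomized before testing) the raw
p-values are approximately uniform once per-bin counts are large enough
for the discrete statistic to be near-continuous (KS distance from uniform
~0.08 at ~1,000 events per species); at smaller counts the doubled
discrete p is conservative, never anticonservative.

## Synthetic guild generator

The generator stands in for dry-season survey data: stations with
deployment windows, per station x species Poisson detection counts (rate x
deployment days), detection dates uniform over deployment days, times of
day from a von Mises mixture.  The default guild has 30 stations, 90 days
and three nocturnal species at 0.11 detections/station-day (~300 events
each): a leopard-like species with a bimodal pattern peaking near 21:30
and 04:30, a lion-like species unimodal near 03:00, and a hyaena-like
species with broad night activity and a pre-dawn bump — magnitudes chosen
to resemble dry-season road-travel activity of a large-carnivore guild
where the spacing analysis operates on a few hundred events per species.

Interactions are injected after the baseline draw, in declared order:
*following* adds, per leader capture, a follower event at lag
|Normal(lag_mean, lag_sd)| hours with probability `p_effect` (additive, so
marginal diel patterns stay approximately intact at small effects — which
is precisely why the spacing test rather than the overlap coefficient is
the detector); *avoidance* deletes follower events inside a refractory
window after a leader capture with probability `p_effect`.  A ledger
records every baseline, injected and deleted event, and emitted records
always equal baseline + injected - deleted.  All randomness flows from one
root seed through fixed `SeedSequence` spawn keys (station x species;
interaction index), so any component regenerates identically.

What the generator does **not** emulate: detection-probability or distance
effects, movement or spatial autocorrelation between stations, seasonal or
lunar trends, weekday structure, or individual identity.  Passing tests
therefore demonstrate that the estimators and tests behave correctly for
independent detections shaped by a diel density — the model the analysis
itself assumes — not that the pipeline is robust to violations of that
model in field data.

## Numerical choices and problem sizes

* Grid size m = 128, rectangle rule on the circle; density evaluation at
  arbitrary angles is the exact kernel sum, not grid interpolation.
* Bessel-function ratios use exponentially scaled Bessels; the ML
  concentration is solved by bracketed root-finding to 1e-10.
* Estimates above 1 by float error clip to 1; ties in the dedup filter
  (identical timestamps, same chain) collapse to the first record in file
  order.
* Default seeds are explicit everywhere (package default 20180901); every
  analysis script and test fixes its seed.
* Monte-Carlo studies in the test suite use deliberately scaled sizes:
  CI coverage at 100 pairs x 1,000 resamples; equality-test calibration at
  200 null pairs x R = 199; spacing family-wise error at 200 simulated
  datasets x R = 200 and spacing power at 20 datasets x R = 1000 (R = 200
  cannot reach Bonferroni significance by the discreteness constraint
  above, so the error-rate check at R = 200 is conservative by
  construction).

## Known limitations

* The spacing test conditions on observed A captures; it measures
  association, not direction of causation (following vs vacating cannot be
  separated without movement data).
* The activity-equality test's null draws smoothed samples from the pooled
  kernel, which is slightly over-dispersed relative to the empirical pool;
  measured calibration is mildly conservative (type-I ~0.035 at nominal
  0.05).
* Dhat4 carries an upward bias of a few hundredths at n ~ 100 for
  moderately overlapping patterns; the recentred interval does not remove
  estimator bias, only the double-counted smoothing shift.
* With very concentrated activity (kernel concentration approaching the
  grid Nyquist scale, kappa ~ several hundred) the 128-point grid
  integration degrades; raise `m` for such data.
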