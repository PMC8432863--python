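# camtraptime

Temporal-interaction analysis for camera-trap detection data, written for
ecologists studying how sympatric species — canonically the members of a
large-carnivore guild — partition the 24-hour day and react to one another
at shared sites.

Given tabular detection records (station, site, species, timestamp,
optional individual id and sex) and station deployment windows, the
package provides every stage of the analysis:

* **Independent capture events** — detections of the same species at the
  same station are filtered so retained events are at least 30 minutes
  apart (earliest capture kept; individually identifiable animals never
  suppress each other), with per-site/species/sex count tables.
* **Diel activity patterns** — circular (von Mises) kernel density
  estimates of time-of-day activity, with a plug-in concentration rule and
  exact smoothed-bootstrap sampling.
* **Coefficient of overlapping** — Δ = ∫ min(f̂, ĝ) over the 24-h circle
  for a species or site pair, estimated by Δ̂₁ (grid integral; smaller
  sample < 75 events) or Δ̂₄ (density ratios at the observed times;
  otherwise), with 95% smoothed-bootstrap confidence intervals
  (logistic-scale correction when a bound leaves [0, 1]) and a > 30-event
  minimum-sample rule.
* **Activity-equality randomization test** — observed overlap against R
  smoothed sample pairs drawn from the pooled kernel;
  p = (#{null ≤ observed} + 1)/(R + 1), reported in tiers (p<.05, p<.001).
* **Temporal-spacing analysis** — for an ordered pair (A, B) at
  co-occurrence stations, minimum times from each A capture to the nearest
  B capture before and after (references with an intervening A capture
  excluded per direction), binned hourly out to ±12 h, against a null that
  re-dates each B detection uniformly within its station's deployment and
  re-times it from B's activity density; per-bin two-sided permutation
  p-values with Bonferroni correction over the bins.
* **Synthetic guild generator** — Poisson detections with von Mises-mixture
  diel activity and injectable following/avoidance structure, plus a
  ground-truth ledger, so every stage above is testable without field data.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
simulated three-species nocturnal guild (30 stations, 90 days, ~300
events per species) — once with independent species and once with the
lion-like species injected to follow the leopard-like species at a ~30 min
lag with probability 0.5:

```sh
python analysis/01_simulate_guild.py     # writes scratch/analysis_data/
python analysis/02_independent_events.py # event filter + count table
python analysis/03_activity_patterns.py  # activity kernels (Fig-2-style curves)
python analysis/04_activity_overlap.py   # overlap matrix + equality tests
python analysis/05_temporal_spacing.py   # spacing permutation tests
```

Output of `04_activity_overlap.py` on the independent guild:

```
hyaena vs leopard: Delta4 delta=0.79 (0.74-0.85), equality p=0.0010 [p<.05]
hyaena vs lion: Delta4 delta=0.86 (0.80-0.93), equality p=0.0020 [p<.05]
leopard vs lion: Delta4 delta=0.71 (0.64-0.77), equality p=0.0010 [p<.05]
```

Each line gives the estimator chosen by the smaller sample size, the
overlap coefficient with its 95% smoothed-bootstrap CI (0 = disjoint
activity, 1 = identical), and the randomization-test p-value for a
difference in activity patterns: the three species overlap substantially
(0.7–0.9, as nocturnal guild members do) yet their distinct peak
structures are detectably different.  And `05_temporal_spacing.py`:

```
[independent] 30 co-occurrence stations, n_ref={'before': 164, 'after': 164}; significant bins: none
[following] 30 co-occurrence stations, n_ref={'before': 240, 'after': 240}; significant bins: [(1, 'above')]
    bin +1: observed=0.671 vs null mean=0.018 (adj p=0.0480)
```

With independent species no bin deviates from the randomization null;
with injected following, the probability of detecting the follower in the
first hour after a leader capture (0.671) far exceeds the null expectation
(0.018) and is the only Bonferroni-significant bin — the analysis
recovers exactly the structure that was planted and nothing else.

The same functionality is exposed as a CLI (`camtraptime simulate | dedup |
counts | overlap | compare | spacing | all`) for running against real
detection CSVs; column names are configurable, and a `skip_dedup` flag
accepts inputs that are already event-filtered.

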