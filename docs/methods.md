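# Methods

## The savings paradigm and its data shapes

The unit of observation is a *list* learned to criterion in `S1` seconds and
relearned after retention interval `t` in `S2` seconds; savings is
`Q = (S1 − S2)/S1`. A *savings curve* is the per-interval aggregate of `Q`
over lists, and model fitting operates on curves, not on raw lists. The
canonical design uses seven intervals (20 min, 1 h, 9 h, 1, 2, 6, 31 days)
with about ten lists each, collected from a single subject over roughly 75
days.

Negative savings are legal observations (relearning can take longer than
learning) and the fitting layer never clips them.

## Retention models

Seven laws are implemented (see README for the equations). Notes on the
non-obvious choices:

* **Power law form.** We use `Q(t) = mu1·(1+t)^(−a1)`. The variant with the
  rate inside the base, `(1+mu1·t)^(−a1)`, also circulates in the
  literature; at the parameter values reported for these savings curves it
  is off by an order of magnitude in SSD, while the `mu1·(1+t)^(−a1)` form
  reproduces the published fits exactly. The alternative is kept as a
  labelled evaluator (`eval_power_printed`) and is not fit. The `+1` offset
  only matters below ~1 s and keeps `Q(0)` finite.
* **Ebbinghaus 1880 law.** Defined for `t ≥ 2` min; at exactly `t = 2` the
  inner bracket is zero and `Q = 1`, below it the base turns negative under
  a fractional power and the evaluator raises a domain error.
* **Boost step.** The boost applies on the half-open interval
  `[86400 s, ∞)` — "one day and higher".
* **MCM degeneracy.** When `|a1 − a2| < 1e−12·max(a1, a2)` the MCM evaluator
  switches to the analytic limit `mu1·e^(−a1 t)·(1 + mu2·t)`, avoiding
  catastrophic cancellation without a visible discontinuity. The MCM curve
  is non-increasing only while `mu2 ≤ a1` (consolidation slower than the
  fast store's decay); all published fits are deep inside that regime.
* **Units.** `eb1880`/`eb1885` parameters are defined for `t` in minutes,
  everything else in seconds. Unit conversion happens once, at the
  model-evaluation boundary; all public interfaces take seconds.

## Fitting

Unweighted least squares (the source analyses give no weighting). Generic
models use multi-start `scipy.optimize.least_squares` with per-model bounds
(amplitudes in `[1e−3, 10]`, rates in `[1e−10, 1]`, boost in `[0, 0.5]`,
wider boxes for the historical minutes-based laws); starts are log-uniform
within bounds, drawn from a generator seeded by the `seed` argument, 50
starts by default. Ties in SSD (within `1e−12`) are broken by the
lexicographically smallest parameter vector so results are reproducible.

Sums of exponentials are notoriously multi-modal in their natural
parameterization, so `summed_exp` is fitted by **variable projection**: for
fixed decay rates the optimal amplitudes solve a non-negative linear
least-squares problem (NNLS), leaving a 2-D search over log-rates
(multi-start Nelder–Mead, then a full 4-parameter polish). Because the MCM
is an exact reparameterization of the summed exponential
(`beta1 = mu1 − mu1·mu2/(a1−a2)`, `beta2 = mu1·mu2/(a1−a2)`), the `mcm` fit
is obtained from the same optimum through the exact inverse map. This is
deliberate: the two families are the same function space and report
identical SSDs — as the published comparison table also shows — while the
eval-level identity is verified independently by property tests over random
parameter draws.

Goodness of fit: `SSD`; uncentered `R² = 1 − SSD/ΣQᵢ²` (the centered form
does not reproduce the published tables, since savings curves are far from
mean-zero); and `AIC = n·ln(2π·SSD/n) + n + 2(k+1)`, the Gaussian
maximum-likelihood form counting the residual variance as one fitted
parameter. This AIC variant reproduces all twenty published (SSD, k, AIC)
triples at their printed precision. A zero SSD yields an `−inf` AIC sentinel
with a warning.

## Interval conventions and source-table discrepancies

Two interval grids exist for the short retention intervals: Ebbinghaus's own
stated 19 min / 63 min / 8.75 h, and the replications' 20 min / 1 h / 9 h.
Refitting shows that **every** published fit — including those to
Ebbinghaus's curve — is reproduced on the uniform replication grid (e.g. the
1880 refit gives 0.5228/0.1010 with SSD 0.002240, matching the published
0.523/0.101/0.00224), whereas on the stated 19/63/525-min grid the
attainable SSD is markedly lower (0.00185). `load_table3()` therefore
defaults to the uniform grid (`intervals="fitted"`) and exposes the stated
per-subject convention as `intervals="stated"`.

Brute-force consistency checks of the published comparison table found a few
cells whose printed SSD disagrees with the value implied by that cell's own
printed parameters by more than one unit in the last printed digit — in two
cases the printed SSD even lies below the global optimum of the objective,
which no fit can reach (verified with 400-start variable projection and
unconstrained amplitudes). The acceptance tests assert those cells
(power/Seitz, boost/Mack, summed-exponential and MCM for Seitz and Dros)
against the recomputed optima and everything else against the printed
values.

## Reduction of raw records

* **Aggregation.** Two conventions exist: savings of the per-interval mean
  times (`pooled`, the default — it is the convention behind the published
  per-interval average rows, which print mean S1, mean S2 and Q
  consistently) and the unweighted mean of per-list Q (`per_list`). They
  differ in the third decimal on real data (e.g. 0.335 vs 0.333 at 1 h).
  The published 6-day average cell prints "0"; both recomputations (0.185
  pooled, 0.181 per-list) identify it as a typographical error and the
  package uses the recomputed value.
* **Drift correction.** Learning time creeps upward across the experimental
  calendar (proactive interference/fatigue); `drift_fit` estimates the slope
  by OLS of `S1` on calendar day. `drift_corrected_savings` projects the
  learning time forward over the retention interval
  (`S1* = S1 + slope·days`) and recomputes `Q' = (S1* − S2)/S1*`. This is
  one plausible reading of the correction used in the literature (the exact
  per-list procedure there is unstated); on the 31-day average times with a
  2.67 s/day slope it gives 0.133 against a reported ≈0.137.
* **Time-of-day normalization.** Morning-session learning is faster;
  learning times from midday (B) and evening (C) sessions are normalized to
  the morning session A by factors 0.95 and 0.87.
* **Summary-statistic ANOVA.** One-way independent ANOVA from per-group
  `(n, mean, SD)` with `SS_between = Σ nᵢ(mᵢ − m̄)²`,
  `SS_within = Σ (nᵢ−1)sᵢ²`, `df = (g−1, N−g)`. On the learning-repetition
  summaries this reproduces `F = 0.691`; note `N − g = 62` here (the source
  prints 69 for the within df, which is `N` minus the number of intervals
  plus one — we follow the standard definition, which does not change `F`).
  Zero within-group variance yields an infinite-F sentinel.

## Serial-position analysis

Per-(interval, position) proportions correct at first relearning, positions
1–13, with lenient scoring (a correct syllable counts for its intended
position) applied upstream. Group slopes are OLS of the group-mean
proportion on the retention interval **in days, untransformed** — days make
the published slope magnitudes (≈ −0.01/day for middle positions, ≈ −0.0002
for the edges) plausible for proportions declining over a month; the
original unit is not stated and the raw per-position data are unpublished,
so the slopes are validated by recovery tests on synthetic data rather than
against printed values. Empty cells are excluded pairwise.

## The synthetic-data generator

`simulate_experiment` emulates the study conditions: 7 intervals, 10 lists
per interval, `S1 ~ N(1840 s + drift·day, 150 s)` truncated at 300 s
(defaults match the real per-interval mean learning times), observation
noise `N(0, 0.03)` added to the true savings (noise on Q, not on S2, because
the fits operate on savings), `S2 = S1(1 − Q_obs)` truncated at 60 s, days
uniform over a 75-day calendar; `massed_longest` reproduces the design
confound in which all 31-day lists were learned in the first ten days. It
does **not** emulate syllable-level stimulus structure, the actual learning
calendar, serial-position heterogeneity within a list, or non-Gaussian
response-time noise — so passing recovery tests show the pipeline is
consistent and calibrated, not that real forgetting follows any particular
law. `simulate_serial` draws per-cell binomial counts under flat
primacy/recency groups and linearly decaying middle groups (baselines
0.9/0.5/0.6/0.9, decays 0/0.01/0.01/0 per day, 80 trials per cell ≈ 10
lists × 8 rows).

All randomness in a simulation flows from the config seed; identical
configs are byte-identical in output.

### Calibration results the tests compute

Parameter recovery (simulate → reduce → fit) is exact at zero noise and
median-unbiased within Monte-Carlo error at observation noise 0.03 over 100
replicates; the median check uses 3 empirical SDs rather than an SE-of-mean
bound because the 4-parameter consolidation model is weakly identified at
n = 7 points and nonlinear least squares is not mean-unbiased at finite
noise. The summary-statistic ANOVA rejects at 5% ± 2% under the null (1000
replicates). Boost-model selection by ΔAIC > 2 detects a Mack-sized 1-day
jump (0.131) in ≥ 80% of replicates at noise 0.02 and stays silent (≥ 80%
non-preference) when the true boost is zero.

## Problem sizes

All fits in the test suite and acceptance script run at the study's own
scale: 7-point curves, 10–50 optimizer starts, 100-replicate recovery
experiments and 1000-replicate ANOVA calibration. The full default suite
completes in about a minute; regenerating the entire model-comparison table
(4 subjects × 7 models × 50 starts) takes a few seconds.

## Known limitations

* The published serial-position slopes and the learning-time drift
  regression (2.67 s/day, 56.18% variance explained) cannot be recomputed
  from printed data — the per-position scores and per-list calendar dates
  are unpublished — and are covered only by synthetic recovery tests.
* Confidence intervals on fitted parameters are out of scope (the source
  analyses report none), as are Bayesian fits and the broader catalogue of
  candidate retention functions.
* The drift correction is an interpretation (see above); alternative
  readings shift the corrected 31-day savings by a few thousandths.
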