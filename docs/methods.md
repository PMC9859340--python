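# Methods

This note documents the models and numerical choices behind the
package, in the order the pipeline runs.

## Expert threshold configuration

The battery comprises 21 features: 3 cardiovascular, 11 muscular and
7 nervous.  Each feature carries an ordered partition of its admissible
value range into 3 or 5 intervals with scores 1–5; 3-level features use
{1, 3, 5} so that the 1–5 scale is preserved.  The bundled encoding
(`data/default_thresholds.json`) is declarative JSON; a user file with
the same schema (JSON or YAML) can replace it.

Conventions that the printed threshold tables leave open:

* **Boundary ownership.** Intervals are half-open `[lo, hi)` with the
  top level closed at the domain maximum, so every value has exactly
  one owning level and boundary values resolve deterministically (a
  Ruffier index of exactly 10 belongs to the `>= 10` band, scored 1).
* **Blood pressure is band-shaped.** For systolic (112–130 mmHg best)
  and diastolic (77–87 mmHg best) pressure the middle interval scores 5
  and the extremes score 1 (low) and 3 (high): both hypo- and
  hypertension are penalized, the former more.
* **Plank asymmetry** is |left − right| side-plank duration in seconds;
  the absolute difference is the only symmetric statistic on the scale
  of the `>90 s` threshold.  It is computed automatically when absent
  from a record and passed through when supplied.
* **Value domains** are generous physical bounds (blood pressure
  50–250 mmHg, durations 0–600 s, mistake counts 0–50), meant to
  reject sensor garbage early rather than encode physiology precisely.
* **Tapping "poverty"** is oriented exactly as its threshold table
  prints it (`>25 %` scores best), although the cohort mean (≈6.5 %)
  sits in the worst band; the orientation is applied consistently in
  the scorer and the simulator.
* Strict validation (3/11/7 subsystem counts, 3-or-5 levels) applies to
  full battery configurations; `FeatureSpec` itself accepts any ≥2-level
  partition so that didactic features (e.g. a single threshold at 25)
  can be built directly.

## Fuzzy scoring

Membership curves are piecewise linear: a *left* side curve (1 below
its threshold, descending ramp), trapezia for interior levels, and a
*right* side curve for the top interval.  The printed form of the right
side curve is internally inconsistent (it would assign membership 1 at
both ends of its own ramp); it is implemented as the mirror image of
the left curve — a rising ramp — which matches the intended geometry.

Transition zones: around each internal threshold *t* the ramp spans
[*t* − h, *t* + h] with halfwidth h = σ/2, where σ is the standard
deviation of the cohort values in the level interval directly above
*t* (sample SD, ddof = 1).  This reproduces the documented worked case
(threshold 25, σ = 8 → ramp on [21, 29]).  Numerical safeguards:

* h is clipped to half the gap to each neighbouring threshold so zones
  never overlap; a zone that would still cross the value-domain edge is
  a configuration error.
* Threshold bins with fewer than 2 subjects (and the no-cohort case)
  fall back to a per-feature default halfwidth stored in the
  configuration, chosen as roughly a quarter of the narrowest adjacent
  interval so plateaus always dominate.
* Discrete mistake counts always use h = 0 (crisp steps): fractional
  mistakes do not exist, and ramps between consecutive integers would
  be degenerate.
* Zero-width ramps degenerate to steps under the same half-open
  convention as the crisp lookup, so the σ → 0 limit of the fuzzy score
  is exactly the table lookup.

Because adjacent ramps share knots, level memberships sum to 1
everywhere (asserted to 1e−9 in tests).  The crisp score is the
membership-weighted mean of the level scores — a first-order weighted
average with singleton consequents, so no output defuzzification is
needed.  At a threshold with symmetric ramps the score is the
arithmetic mean of the two adjacent level scores.

`FuzzyScorer` wraps this as a scikit-learn transformer: `fit`
estimates the halfwidths from a reference cohort, `transform` scores
any cohort on the fitted curves, and `score_table` appends the three
subsystem grade sums and the 21-to-105 total.

## Quartile labeling

Quartiles sit at ranks (n+1)/4 and 3(n+1)/4 of the sorted grades, with
linear interpolation at fractional ranks and clamping to [1, n].
Classes: C1 = grade < Q1, C2 = [Q1, Q3), C3 = grade ≥ Q3 — the upper
quartile itself counts as good health, which also fixes the degenerate
constant-grade cohort (everyone C3, with a warning).  At least 4
subjects are required.  Labels are cohort-relative by design; with
`per_system=True` each subsystem's grade sums are split independently
of the overall split (a deliberate interpretation — the alternative,
reusing the overall split, is available by labeling on `total` only).

## Classification metrics

The 3×3 confusion matrix uses rows = actual, columns = predicted; per
class, TP is the diagonal entry, FP the rest of the column, FN the rest
of the row.  Micro precision/recall/F1 pool the counts and therefore
all equal the diagonal sum over the total — i.e. overall accuracy —
in this single-label setting; the identity is kept numerically exact.
Macro metrics average per-class ratios unweighted; classes with a zero
denominator contribute 0 with a warning.  `accuracy` is diagonal/total;
a variant that normalizes by TP + FP + FN (double-counting each error)
is kept as `accuracy_error_normalized` for comparison only, since it
disagrees with the micro identity whenever errors exist.

## Random-forest protocol

Per iteration: stratified 70/30 train/test split (unstratified fallback
with a warning when a class has < 2 members), a 100-tree forest with
entropy splits, and a 5-fold stratified CV score on the training part
reported purely as an overfitting diagnostic — nothing is tuned on it.
Fifty iterations by default; both the split and the forest are
re-seeded per iteration from a deterministic `SeedSequence` of the
master seed, making the whole experiment reproducible.  Averages are
arithmetic means of the per-iteration metrics.

Feature-importance filtering (mean impurity-based importance < 0.05)
is applied only to the all-features model, reported as the retained
feature list; subsystem models keep their 3/11/7 features.  If nothing
survives the filter, all features are kept with a warning.  Tree depth
is unlimited and the forest size (100) is a conventional default; both
are exposed in `TrainConfig`.

## Synthetic cohorts

The simulator emulates the reference cohort's marginal statistics
(printed means ± SDs; n = 98 by default, with 57/41 female/male and
age 38.0 ± 11.8 years generated as inert metadata).  A single latent
standard-normal health factor h couples the features:

    value = mean + SD · (orientation · λ · h + sqrt(1 − λ²) · ε)

with loading λ ∈ [0, 1] (default 0.6, a moderate correlation typical of
fitness test batteries; benchmark tests use 0.9 for a strong, clearly
learnable signal and 0 for the null).  Orientations follow the healthy
direction of each threshold table; the two blood pressures get
orientation 0 because their optimum is an interior band that a linear
factor cannot express.  Left/right pairs share half of their noise
variance so asymmetry features stay realistic.  Out-of-domain draws are
resampled (idiosyncratic noise only) to avoid boundary atoms; discrete
counts are rounded to integers, with the bound check applied after
rounding.

What the simulator does *not* emulate: the real joint distribution of
the battery (unknown), covariate effects of sex/age/occupation, sensor
noise and measurement drift, and any non-Gaussian shape of the real
marginals.  Consequently, passing recovery tests shows the pipeline is
correct and sensitive, not that the reported real-cohort accuracies
transfer.  One structural consequence worth noting: because the class
labels are quartile splits of the score sums, they are deterministic
functions of the very features the forests see, so synthetic
classification accuracies are optimistic by construction; chance-level
(≈ 1/3) behaviour is verified against shuffled labels and against the
latent terciles at λ = 0.

A further tension inherited from the printed statistics: the
closed-eyes balance counts (≈ 3.0 ± 2.6 mistakes, support ≥ 0) place
about 9 % of their Gaussian mass below zero, so truncation moves more
than the ≤ 5 % of mass it moves for every other feature; the tests
assert a 10 % ceiling for those two features and 5 % elsewhere.

## Reporting

Hexagon-web axes (the six-axis radar): cardiovascular sum; trunk
endurance (back + abdomen); planks (left + right + asymmetry); legs and
transitions (leg strengths, sit-down, bend, turn-overs); static
balance (four mistake counts); tapping (mobility, poverty, mistakes).
Axis sums are min–max scaled against the reference cohort (the exact
scaling is not prescribed anywhere; min–max is the simplest choice that
pins the cohort extremes to 0 and 1), with the cohort median as the
norm value.  Asymmetry flags fire when a left/right score pair differs
by ≥ 2 points.  Recommendations are template-based: C3 everywhere →
maintenance; each subsystem at C2 or worse → a 4-week training plan
plus a retest instruction; any C1 → a doctor-referral flag.  The
referral flag is monotone in worsening classes.

## Problem sizes in the shipped tests

The test suite exercises cohorts of 4–5000 subjects (5000 only for
marginal-fidelity checks), 1000-point grids per feature for the
partition-of-unity and monotonicity properties, 200 random cohorts for
the quartile oracle, 200 random label vectors for the metrics oracle,
and 10-iteration forest experiments at n = 300 for the recovery checks
— sizes at which every statistical assertion is stable across seeds
while the whole suite stays fast.
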