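# Methods

This note records the model, the numerical choices, and the limits of
what the synthetic experiments demonstrate.

## The labelling model

The pipeline treats change-point labelling as a three-stage inference:
many noisy human annotations → cleaned per-person line sets →
density-consensus labels, validated against a single expert annotator.

**Aggregation.** An extract is a typed record table with exactly one
timepoint field.  Rows with a missing or unparseable timepoint are
excluded outright (they cannot be binned); exact duplicate rows are
removed keeping one, with the removed count kept as its own
(`DUPLICATES`) series.  Intervals are day (midnight to midnight),
week (Monday to Sunday, pandas `W-SUN` periods), and calendar month,
and every emitted series has a gap-free interval index spanning the
extract's date range.  Per interval:

- *missingness*: a value is missing if null or an empty/whitespace-only
  string (this includes Freetext fields — an empty note is treated as
  absent).  `missing_perc = 100·missing_n/(missing_n+n)`, so
  `missing_n + n` always equals the interval's record count.
- *conformance*: defined for Numeric and Datetime fields only — a
  present value that does not parse as a number/date.  Its percentage
  denominator is the count of present values (conformant +
  nonconformant), keeping every percentage in [0, 100].
- *plausibility*: min/max/mean/median over conformant numeric values
  (Datetime extremes are stored as fractional days since 1970-01-01 so
  they remain plottable); distinct and per-subcategory counts for
  categorical fields, suppressed when the field has ≥ 20 categories
  (the limit is configurable to admit wider coded fields);
  `midnight_n` counts timestamps whose time-of-day is exactly 00:00:00
  and is only emitted for fields declared to carry a time element.
- empty intervals give `n = 0` (a genuine observation of "no records")
  and NA for every other function, which cannot be evaluated there.
- the `ALL_DATA` pseudo-field pools values over all non-timepoint
  fields; its nonconformance pools over the fields where conformance is
  defined.  `DUPLICATES.nonzero_perc` uses removed-duplicates /
  (kept + removed) rows per interval as the denominator — the simplest
  reading of "percentage of records that had been duplicated".

**Geometry.** Images are 1000×666 px at 96 dpi with a fixed plot area.
The plot-area width is 952 px: with the 7 px cutoff this gives exactly
⌊952/7⌋ = 136 candidate change-point slots per image, the constant the
true-negative estimate needs (286 × 136 − 492 − 90 − 120 = 38,194
checks out against the validation arithmetic).  Margins (left 24 px,
top 20 px) are a package choice; only the plot-area width is
load-bearing.  The date↔pixel map is affine on [date_min, date_max] →
[left, right]; the inverse snaps to the nearest interval start so
labels index real timepoints.  Axis rules: count-type series are drawn
from 0 to max(10, data max), percentages 0–100, subcategory counts on
the whole-field count scale, other values free-scaled.

**Cleaning.** First attempt per person per image (ordered by attempt
timestamp, ties by classification id), then the 41 earliest-classifying
people per image.  Same-person lines strictly closer than 7 px are
merged transitively — connected components of the `<7 px` graph, which
in one dimension are maximal runs of sorted positions with consecutive
gaps < 7 — at their unweighted mean, green if any contributor was
green.  Component merging is the only order-independent choice and it
is idempotent: adjacent merged components are separated by ≥ cutoff, so
their means are too.

**Consensus.** 1-D DBSCAN, written exactly: a core point has ≥ minPts
points (itself included) within eps, *inclusive* (`≤ eps`), matching
the definition of eps as the maximum distance between two lines in a
cluster; note the cleaning cutoff is exclusive (`< 7 px`) because 7 px
apart is documented as two distinct change points.  Clusters are
numbered left to right.  A border point joins its nearest core point's
cluster, ties to the lower cluster id — the tie rule is unstated
upstream, and this is the deterministic choice.  In sorted order the
whole computation is two `searchsorted` passes plus a scan, O(n log n);
tests verify exact agreement with a quadratic brute-force reference and
with scikit-learn's DBSCAN on the border-rule-independent parts (core
set, noise set, core partition).  Default parameters are the tuned
values: exclude yellow lines, minPts = 5, eps = 3 px.

**Evaluation.** Matching is strict-`<` at the 7 px cutoff, consistent
with the cleaning rule.  The per-expert-line / per-label counting
satisfies both double-counting rules by construction (x labels near one
expert line: 1 TP, 0 FP; one label near two expert lines: 2 TP, 0 FN).
Counts are pooled across images before metrics, matching how final
performance is reported.  CIs are Wilson score intervals (z = 1.96);
they reproduce all printed interval bounds of the worked example, which
is why Wilson was chosen over Wald or Clopper–Pearson.  MCC is defined
as 0 when any marginal sum is 0.  The tuning grid is
{include, exclude yellow} × minPts 2..20 × eps 1..7 px = 266 points,
ranked by pooled MCC with deterministic tie-breaks (smaller minPts,
smaller eps, exclude-yellow first).  The 70/30 split is stratified by
extract with round-half-up per stratum; with the validation study's
per-extract daily image counts (167, 401, 184, 204) it yields 670/286.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: 41 volunteers per
image (the retirement threshold), detection probability 0.8 per change
point, Gaussian pixel jitter with SD 2 px, 10% uncertain (yellow)
lines, 0.3 spurious uniformly-placed lines per volunteer per image, and
optional repeat classifications to exercise first-attempt filtering.
No per-extract behavioural statistics are published, so detection,
jitter and noise rates are plausible round values chosen once, not
calibrated.  Volunteers are i.i.d.; there is no per-volunteer skill,
attention drift, or position bias, and no modelling of the platform's
scheduling beyond repeats.

Record extracts use simple baselines (Numeric ~ N(50, 10), uniform
categories, sequential identifiers, 5% missingness) with artefact
magnitudes in baseline SDs; a trend adds magnitude·SD per 30 days, an
outlier occupies a single timepoint, a presence artefact empties a
configurable run of days.  Real EHR values are heavy-tailed,
discretised and autocorrelated; passing tests therefore demonstrate
that the *pipeline machinery* (cleaning, clustering, matching,
tuning) is correct and that recovery is high under the stated noise
model — not that crowd annotators achieve any particular accuracy on
real hospital data.  The dataset-scale results (thousands of series and
change points, the tuning table on real classifications) require the
deposited study data, which the readers can feed through the same
classification-export reader.

## Numerical choices and degenerate inputs

- Problem sizes: the recovery study uses 200 replicates of 3 truths
  ≥ 21 px apart on a one-year daily image; oracle-equivalence checks use
  1,000 random instances (n ≤ 60 positions; ≤ 20 lines per image for
  matching).  These sizes give stable estimates while keeping the whole
  suite under a minute per file.
- Recovery is declared when a label lies within eps (3 px) of the truth
  pixel; over 200 replicates the observed rate is well above the 90%
  the test asserts.
- Degenerate inputs: an empty line table yields empty outputs at every
  stage; an image whose lines are all yellow yields zero labels under
  the tuned parameters; fewer total lines than minPts yields zero
  labels; a single-image extract stratum triggers a warning and goes
  wholly to tuning; `intervals_per_image` too small for an image's call
  count raises rather than silently clamping TN at zero.
- All randomness flows through `numpy.random.default_rng` seeds;
  identical configs and seeds reproduce identical CSV bytes.

## Known limitations

- The specificity/NPV CIs treat interval-slots as independent
  Bernoulli trials; clustering of slots within images is ignored.
- The true-negative count is an estimate by construction (slots minus
  calls), inheriting the 136-slot discretisation.
- Rendering reproduces geometry and axis rules, not the exact visual
  styling volunteers saw; annotation simulation happens in pixel space
  directly, bypassing human perception entirely.
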