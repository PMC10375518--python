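# crowdcp

Crowdsourced change-point labelling for EHR data-quality time series.

Routinely collected electronic health records drift: computer-system
migrations, new test methods, or changed coding practice put abrupt
*change points* into otherwise smooth time series, and analyses that
ignore them draw wrong conclusions.  One scalable way to build
gold-standard change-point labels is to render data-quality summary
series as plots, have many volunteers draw vertical lines where they see
abrupt changes, and distil those noisy annotations into consensus
labels.  `crowdcp` implements that whole pipeline for researchers who
want to produce, or benchmark against, such labels:

1. **Aggregation** — a typed record extract (one timepoint field plus
   Numeric / Categorical / Datetime / UniqueIdentifier / Freetext
   fields) becomes a family of per-interval series at day, Monday–Sunday
   week, and calendar-month granularity: counts `n`, `missing_n` /
   `missing_perc`, `nonconformant_n` / `nonconformant_perc`, min / max /
   mean / median, string lengths, distinct and per-subcategory counts,
   plus whole-extract and duplicate-row summaries.  Empty intervals give
   `n = 0` and NA for every other function.
2. **Rendering** — each series is plotted to a fixed 1000×666 px canvas
   (96 dpi) with fixed axis rules (counts start at 0 and end no earlier
   than 10; percentages span 0–100), and the affine pixel↔date mapping
   is recorded in a manifest so a drawn x-pixel converts back to a date.
3. **Cleaning** — per image, only each person's first classification
   counts, capped at the 41 earliest people; lines drawn by the *same*
   person closer than the 7 px minimum-distance cutoff are merged at
   their mean (green beats yellow).
4. **Consensus** — per image, the cleaned line positions are clustered
   with 1-D density-based clustering with noise (DBSCAN): a core point
   has ≥ `minPts` lines within `eps`; clusters are connected core points
   plus borders; noise is discarded.  The cluster mean pixel, converted
   back to a date, is the consensus change-point label.  The clusterer
   is exposed as a scikit-learn estimator (`DBSCAN1D`).
5. **Evaluation** — consensus labels are scored against expert lines as
   an approximate binary classifier: an expert line with a label within
   the cutoff is a true positive, an unmatched expert line a false
   negative, an unmatched label a false positive, and true negatives are
   estimated per image as the 136 cutoff-width intervals of the 952 px
   plot area minus the other counts.  Sensitivity, specificity, PPV and
   NPV carry Wilson 95% CIs, and the Matthews correlation coefficient

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

   drives a grid search over include-yellow × minPts ∈ [2, 20] ×
   eps ∈ [1, 7] px (266 combinations) on a stratified 70/30 image split.
6. **Synthetic data** — a generator produces record extracts with
   injected change points of the five kinds annotators are trained on
   (level, trend, variability, presence/absence, outliers) and simulates
   volunteer behaviour (detection probability, pixel jitter, uncertain
   colours, spurious lines, repeat classifications), so the full
   pipeline is testable without access to clinical data.

## Worked example

Feeding a test set's pooled confusion counts (492 true positives,
38,194 true negatives, 90 false positives, 120 false negatives) through
the metrics module:

```sh
crowdcp metrics --tp 492 --tn 38194 --fp 90 --fn 120
```

```json
{
  "sensitivity": 0.803921568627451,
  "specificity": 0.9976491484693345,
  "ppv": 0.845360824742268,
  "npv": 0.9968679855927337,
  "mcc": 0.8216483137327063,
  "ci_95": {
    "sensitivity": [0.770611466367102, 0.8334401035164223],
    "specificity": [0.9971115694921613, 0.9980868681367028],
    "ppv": [0.8137309582832056, 0.8724615157168948],
    "npv": [0.9962564883248961, 0.9973798583601658]
  }
}
```

Read: the crowd found 80.4% of the expert's change points (95% CI
77.1–83.3%), 84.5% of crowd labels matched an expert line, and the MCC
of 0.822 summarises the heavily imbalanced 2×2 table (most of an image
contains no change point, hence the high specificity and NPV).

A full synthetic pipeline run, from record generation to the tuning
grid:

```sh
crowdcp all --config examples/pipeline.yaml --workdir out/
```

writes `records.csv`, `series.csv`, the rendered `images/` and their
coordinate `manifest.csv`, raw/cleaned line tables, `labels.csv`,
`metrics.json` and the 266-row `grid.csv`, plus a `manifest.json` with
seeds and artefact hashes; re-running with the same config and seed
reproduces the CSVs byte for byte.

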