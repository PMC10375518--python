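# Synthetic end-to-end pipeline configuration.
seed: 7
extract_id: synthetic
date_span: ["2019-01-01", "2019-12-31"]
records_per_day: 20
missing_rate: 0.05
granularities: [day]
subcategory_limit: 20
fields:
  - {name: spec_date, type: Timepoint}
  - {name: value, type: Numeric}
  - {name: category, type: Categorical, subcategories: [A, B, C]}
truths:
  - {date: "2019-05-01", kind: level, magnitude: 6}
  - {date: "2019-09-01", kind: variability, magnitude: 3}
volunteer_model:
  n_volunteers: 41
  detect_prob: 0.8
  jitter_sd: 2.0
  noise_rate: 0.3
  uncertain_prob: 0.1
  repeat_prob: 0.05
consensus_params: {include_yellow: false, min_pts: 5, eps_px: 3}
cutoff_px: 7
intervals_per_image: 136
render_functions: [n, mean]
render_png: true
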