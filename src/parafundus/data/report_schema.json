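{
 "description": "Required structure of the cohort analysis report emitted by cmd_analyze",
 "required": {
  "seed": "integer",
  "config_hash": "string",
  "n_eyes_total": "integer",
  "n_failed_images": "integer",
  "failed_eye_ids": "array",
  "n_excluded_undeterminable": "integer",
  "n_eyes_analyzed": "integer",
  "pattern_comparison": {
   "t": "number",
   "p": "number",
   "mean_a": "number",
   "sd_a": "number",
   "n_a": "integer",
   "mean_b": "number",
   "sd_b": "number",
   "n_b": "integer"
  },
  "perfusion_comparison": {
   "t": "number",
   "p": "number",
   "mean_a": "number",
   "sd_a": "number",
   "n_a": "integer",
   "mean_b": "number",
   "sd_b": "number",
   "n_b": "integer"
  },
  "contingency": {
   "table": "array",
   "chi2": "number",
   "p": "number"
  },
  "roc_parallelism": {
   "auroc": "number",
   "ci95": "array",
   "p_vs_half": "number",
   "cutoff": "number",
   "sensitivity_pct": "number",
   "specificity_pct": "number",
   "lr_pos": "number_or_null",
   "lr_neg": "number_or_null",
   "sens_at_spec90_pct": "number",
   "sens_at_spec95_pct": "number",
   "positive_means_low_score": "boolean",
   "n_positive": "integer",
   "n_negative": "integer"
  },
  "sample_size_note": {
   "n_nonischemic": "integer",
   "n_ischemic": "integer",
   "total": "integer",
   "method": "string"
  }
 }
}
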