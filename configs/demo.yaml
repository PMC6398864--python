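# Demo run: 2,000 synthetic patients with channeling and a true HR of 0.5.
sim:
  n_patients: 2000
  seed: 7
  vocab_size: 500
  n_proxy_words: 50
  proxy_strength: 0.8
  channeling_strength: 1.0
  true_log_hr: -0.6931471805599453   # log 0.5
  confounder_log_hr: 0.8
  baseline_hazard: 0.0005
lookback_days: 183
freq_threshold: 50      # scaled for the demo cohort size (paper-scale: 1000)
chisq_alpha: 0.05
penalty: 0.01
cv_k: 3
cv_seed: 0
caliper: 0.01
age_tolerance: 2.0
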