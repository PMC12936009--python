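{
 "simulate": {
  "n_responders": 14,
  "n_nonresponders": 15,
  "n_sessions_per_subject": 20,
  "session_duration": 300.0,
  "sampling_rate": 8.138,
  "effect_slope": 0.45,
  "artifact_rate": 2.0
 },
 "preprocess": {
  "band": [
   0.01,
   0.09
  ],
  "filter_order": 6,
  "iqr_factor": 1.5,
  "dpf": [
   6.0,
   6.0
  ],
  "distance_cm": 3.0
 },
 "network": {
  "trials": 15,
  "trial_pool": 20
 },
 "scoring": {
  "alpha": 0.05,
  "normalization": "pooled"
 },
 "fit": {
  "alpha": 0.05,
  "cutoff": 0.35
 },
 "validate": {
  "alpha": 0.1,
  "cutoff": "optimize",
  "optimize_cutoffs": true
 },
 "permtest": {
  "n_perm": 10000
 }
}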