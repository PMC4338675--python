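# Noise-mask configuration: 4x4 hypercolumns, 16 minicolumns each,
# 18 random orthogonal attractor memories of 10 minicolumns per area,
# 20 ms target / 60 ms metacontrast noise mask in shared hypercolumns.
schema_version: 1
experiment:
  model_id: model1
  scale: 1.0
  feedback: true
  mask_points: 4
  soas: [20.0, 40.0, 60.0, 80.0, 100.0, 120.0]
  spacing_ms: 1000.0
  settle_ms: 100.0
  target_duration_ms: 20.0
  mask_duration_ms: 60.0
  relay_rate_hz: 50.0
  n_individuals: 5
  n_trials: 5
  n_patterns: 18
  pattern_size: 10
  target_points: 4
  dt_ms: 0.1
wiring:
  lateral_profile: [1.0]
  exc_scale: 1.0
  inh_scale: 1.0
background:
  rate_hz: 300.0
  weight_uS: 0.0021
  interneuron_factor: 0.5
criterion:
  min_spikes_per_minicolumn: 10
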