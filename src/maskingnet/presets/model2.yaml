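# Line-mask configuration: 9x9 hypercolumns, 8 minicolumns each,
# 72 vertical-line feature detectors of 9 minicolumns per area,
# 20 ms target line / 50 ms flanking mask lines, lateral inhibition
# extending 1-2 hypercolumns horizontally.
schema_version: 1
experiment:
  model_id: model2
  scale: 1.0
  feedback: true
  mask_distance: 2
  target_column: 4
  soas: [20.0, 40.0, 60.0, 80.0, 100.0, 120.0]
  spacing_ms: 1000.0
  settle_ms: 100.0
  target_duration_ms: 20.0
  mask_duration_ms: 50.0
  relay_rate_hz: 50.0
  n_individuals: 5
  n_trials: 5
  dt_ms: 0.1
wiring:
  lateral_profile: [1.0, 0.5, 0.25]
  w_feedforward: 0.033
  w_longrange: 0.016
  ff_l23_ratio: 0.45
  w_recurrent: 0.003
  nmda_ratio_recurrent: 1.8
  exc_scale: 1.0
  inh_scale: 1.0
background:
  rate_hz: 300.0
  weight_uS: 0.0021
  interneuron_factor: 0.5
criterion:
  min_spikes_per_minicolumn: 10
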