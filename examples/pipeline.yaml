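seed: 1
out_dir: semsr_out
simulate:
  n_train_fields: 8
  n_test_fields: 4
  field_px: 128
  n_particles: 12
prepare:
  patch_size: 32
  filter_threshold: 0.4
train:
  iterations: 600
  batch_size: 4
  depth: 2
  base_channels: 8
evaluate:
  n_spectrum_bins: 48
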