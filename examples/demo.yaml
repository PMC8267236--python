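# Reduced-width demo configuration for the phantom worked example.
optimizer: adam
learning_rate: 0.0003
batch_size: 8
max_epochs: 60
early_stop_patience: 20
seed: 0
loss:
  alpha: 0.5
  lambda1: 0.4
  lambda2: 0.2
  epsilon: 1.0e-05
net:
  base_channels: 8
  n_stages: 4
  in_channels: 4
  n_region_channels: 3
  dilation_rates: [6, 12, 18]
  daf_variant: DAF1
  attention_scale_init: 0.0
  msc_positions: [1, 2, 3, 4]
  eds_supervision: true
  us_supervision: true
  seed: 0
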