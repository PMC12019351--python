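# Full-scale profile: depth-6 encoder-decoder, 1000 epochs, batch 64,
# 25 attack iterations, 13-pixel surface tolerance. Requires far more
# compute than the desk profile.
profile: paper
scene:
  height: 512
  width: 512
model:
  depth: 6
  base_channels: 32
train:
  epochs: 1000
  batch_size: 64
  lr_ini: 0.01
  eta: 0.7
  momentum: 0.95
  adversarial:
    epsilon: 0.08
    steps: 25
    enabled: true
metrics:
  tolerance: 13.0
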