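# Desk-scale profile: small model and budgets that fit a single CPU.
profile: desk
scene:
  height: 64
  width: 64
  n_classes: 2
  noise_sd: 0.05
  seed: 0
data:
  n_total: 200
  labelled_fraction: 0.10
  n_test: 40
model:
  depth: 2
  base_channels: 8
  n_classes: 2
  seed: 0
train:
  epochs: 30
  batch_size: 8
  lr_ini: 0.01
  eta: 0.7
  momentum: 0.95
  seed: 0
  pseudo:
    temperature: 0.5
    threshold: 0.8
  adversarial:
    epsilon: 0.08
    steps: 3
    enabled: true
  loss:
    rampup_epochs: 10
    w_max: 1.0
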