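# Desk-scale profile: a small instance of the same architecture that
# trains in well under a minute on one CPU and still learns the synthetic
# task.  Use this for local experimentation and CI-style runs.
model:
  K: 2
  M: 1
  N_enc: 2
  r: 0.5
  D: 32
  h: 2
  ffn_mult: 4
  C: 2
  img_size: [64, 64]
  seed: 0
train:
  lr: 1.0e-3
  weight_decay: 5.0e-4
  batch_size: 8
  epochs: 20
  seed: 0
data:
  n_per_class: 34
  n_classes: 2
  img_size: [64, 64]
out_dir: runs/desk
seed: 0
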