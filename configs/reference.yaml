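# Reference-scale profile: the full architecture and training protocol
# (K=3 blocks, MRI depth 3 / PET depth 1, r=0.5, 224x224 input; Adam,
# lr 1e-5, weight decay 5e-4, batch 128, 300 epochs).  Not desk-runnable
# in reasonable time on one CPU; kept for fidelity and for GPU-class ports.
model:
  K: 3
  M: 1
  N_enc: 3
  r: 0.5
  D: 192
  h: 4
  ffn_mult: 4
  C: 2
  img_size: [224, 224]
  seed: 0
train:
  lr: 1.0e-5
  weight_decay: 5.0e-4
  batch_size: 128
  epochs: 300
  seed: 0
data:
  n_per_class: 150
  n_classes: 2
  img_size: [224, 224]
out_dir: runs/reference
seed: 0
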