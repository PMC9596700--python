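# Scaled-down reference experiment: 10 identities x 20 exemplars at
# 32x32 px, 16 individuals, 150 epochs with checkpoints at 30
# (partially trained) and 150 (well trained).
train:
  n_identities: 10
  image_size: 32
  epochs: 150
  checkpoint_epochs: [30, 150]
exemplars_per_identity: 20
n_individuals: 16
n_replicates: 10
n_trials: 50
cluster_restarts: 10
n_virtual_samples: 50
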