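# gazehmm

Joint modelling of eye-movement strategies and perceptual learning in
face recognition, plus the EMHMM analysis stack used to characterise
those strategies.

## The scientific problem

Adults who look at the eyes during face recognition tend to perform
better; in children this link is absent, and eye-movement *consistency*
across trials appears to matter more.  One mechanistic account: learning
to recognise faces means jointly discovering *where to look* (a visual
routine) and *what to extract there* (a perceptual representation).
Early in learning, how far an individual has converged on a stable
routine — not which routine — predicts performance.

`gazehmm` implements a simulated-individual model of this process:

* **Gaze strategy (HMM).**  An individual's strategy is a hidden Markov
  model whose states are regions of interest (ROIs), each a Gaussian
  over fixation position (x, y, pixels) and a spatial-frequency scale
  coordinate s.  The chain is deterministic (prior (1,0,0), transitions
  1→2→3), so a trial is T = 3 fixations, one per ROI.  Sampled
  fixations get isotropic saccade noise (SD 3 px ≈ 0.375° at
  8 px/degree).
* **Foveated perception (CNN + MLP).**  Each fixation places Gaussian
  attention masks (SD = half the attention window; windows 8/16/32 px
  for 32/16/8 cycles/face) on a 3-level average-pooling image pyramid.
  Per level a small CNN (two valid 3×3 conv layers, 8 then 16 channels,
  ReLU, unit-norm filters) extracts features; a visual short-term
  memory accumulates them across fixations by element-wise maximum; a
  shared 2-layer MLP (40 hidden units, softmax) predicts the identity
  after every fixation.  At the reference 64×64 / 100-class
  configuration the CNN has 3 744 parameters and the MLP 2 902 060.
* **Joint learning.**  The loss is a weighted sum of the per-fixation
  cross-entropies (first fixation weighted most) plus an L2 penalty on
  MLP weights and a centre bias on ROI positions.  Fixations are
  sampled with the reparameterization trick, so Adam updates flow into
  the ROI means and covariance factors as well as the network: strategy
  and representation are learned together.
* **EMHMM analysis.**  Fixation data (simulated or human CSV) are
  summarised per individual by a variational-Bayes Gaussian HMM with
  automatic ROI-count selection (preset range 1–6, many restarts,
  highest lower bound wins).  Individual HMMs are clustered into two
  representative patterns (virtual-sample hierarchical EM, median-ROI
  rule); each individual gets an AB pattern scale
  (A − B)/(|A| + |B|) from its data log-likelihood under the two
  representatives, and an overall entropy — the joint entropy of a
  3-fixation sequence, H(Z₁) + Σₜ E[H(Zₜ|Zₜ₋₁)] + Σₜ Σ_z P(Zₜ=z)·h(𝒩_z)
  in nats — as the consistency measure (lower = more consistent).

Synthetic face-like stimuli (parametric ellipse-composite faces with
identity-diagnostic geometry at the eyes, nose and mouth, 90/10
stratified split) make the whole experiment runnable at desk scale.

## Worked example

Train one simulated individual on 4 synthetic identities and inspect
its strategy at an early and a late checkpoint:

```python
import numpy as np
from gazehmm import (
    TrainConfig, generate_identity_prototypes, render_stimulus_set,
    initialize_individual, train_individual, evaluate_accuracy, overall_entropy,
)

cfg = TrainConfig(n_identities=4, image_size=32, epochs=30,
                  checkpoint_epochs=(5, 30), seed=0)
protos = generate_identity_prototypes(4, rng_seed=0, image_size=32)
stimuli = render_stimulus_set(protos, exemplars_per_identity=12, rng_seed=1)

ind = initialize_individual(cfg, seed=7)
train_individual(ind, stimuli)

for epoch in (5, 30):
    strategy = ind.checkpoint_strategy(epoch)
    net = ind.checkpoint_net(epoch)
    acc = evaluate_accuracy((net, strategy), stimuli, seed=0)
    ent = overall_entropy(strategy, T=3)
    print(f"epoch {epoch:3d}: accuracy {acc:.2f}  entropy {ent.total:.2f} nats")

for t, roi in enumerate(ind.strategy().rois, 1):
    sd = np.sqrt(np.diag(roi.covariance))
    print(f"ROI {t}: centre ({roi.mean[0]:.1f}, {roi.mean[1]:.1f}) px, "
          f"spatial SD ({sd[0]:.1f}, {sd[1]:.1f}) px")
```

Output:

```
epoch   5: accuracy 0.35  entropy 26.21 nats
epoch  30: accuracy 1.00  entropy 19.59 nats
ROI 1: centre (18.1, 24.3) px, spatial SD (1.2, 2.4) px
ROI 2: centre (21.3, 10.8) px, spatial SD (1.1, 1.9) px
ROI 3: centre (12.5, 24.7) px, spatial SD (4.8, 7.5) px
```

Training sharpened the initially large random ROIs (initial spatial SD
is a quarter of the image) into small ones — ROI 2 landed on the eye
region (the eyes sit near y ≈ 11 px at this resolution) — while
validation accuracy rose from chance-level 0.35 to 1.00 and the
strategy's entropy fell from 26.2 to 19.6 nats: the individual acquired
a consistent, diagnostic visual routine.

The cohort-level experiment (train many individuals, cluster their
strategies at an early and a late checkpoint, relate accuracy to the AB
pattern scale and to entropy) runs from the command line:

```sh
gazehmm experiment --fast --seed 0 --out runs/experiment
gazehmm power ttest --d 0.8 --alpha 0.05 --power 0.8 --one-tailed   # prints 42
gazehmm power regression --predictors 2 --f2 0.15                   # prints 68
```

Other subcommands: `generate-stimuli`, `train`, `cohort`,
`simulate-fixations`, `fit-hmm`, `cluster`, `entropy`
(see `gazehmm --help`).

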