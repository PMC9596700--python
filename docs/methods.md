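# Methods

## The generative gaze model

An individual's strategy is an HMM whose hidden states are regions of
interest (ROIs).  State t has a Gaussian emission over
(x, y, s) — fixation position in pixels (0-based, origin top-left,
positions refer to pixel centres) and a continuous spatial-frequency
scale coordinate.  The reference configuration fixes the prior at
(1, 0, 0) and the transitions to the chain 1→2→3, so the state sequence
is deterministic and a trial is exactly T = 3 fixations; transition
learning (e.g. via Gumbel-Softmax relaxations) is deliberately out of
scope.  An observed fixation is

    f = μ_t + L_t ε + δ,   ε ~ N(0, I₃),  δ ~ N(0, σ_sacc² I₂ on x,y),

with L_t a lower-triangular factor of the ROI covariance and
σ_sacc = 3 px of saccade (motor) noise — 0.375° at the fixed conversion
of 8 px/degree.  Saccade noise is applied during both training and
evaluation.  Fixations falling outside the image are clipped to its
bounds (gradients pass through unclipped coordinates only).

The scale coordinate is mapped to the three pyramid levels
(32, 16, 8 cycles/face at levels 0, 1, 2) by Gaussian responsibilities

    w_ℓ ∝ exp(−(s − ℓ)² / (2τ²)),  τ = 0.5 by default,

normalised with a max-subtraction so the normaliser cannot underflow.
Soft weights keep the level selection differentiable; a hard
per-fixation spatial frequency is recovered as the argmax level.  Each
level ℓ receives the attention mask

    m_ℓ(p) = w_ℓ · exp(−‖p − loc/2^ℓ‖² / (2σ_ℓ²)),

whose peak equals the scale weight.  The full-resolution mask SD is
half the attention window (windows 8/16/32 px for the three spatial
frequencies), which equals σ_ℓ = 4 px in every level's own pixel grid.

## Perception and the joint objective

Each masked pyramid level passes through its own two-layer CNN
(3×3 kernels, valid mode, 8 then 16 channels, ReLU), shared across
fixations.  Features accumulate across fixations into a visual
short-term memory by element-wise maximum (so evidence can only
strengthen), and a shared MLP (40 hidden units, ReLU; softmax output)
predicts the identity after each fixation.  The reference 64×64 /
100-class configuration yields the parameter counts 3 744 (CNN) and
2 902 060 (MLP); these anchor the pyramid sides (64/32/16), the valid
convolutions, bias inclusion, and the flattened feature dimension
(60² + 28² + 12²)·16 = 72 448.

The training loss for one image is

    Σ_t w_t · CE_t  +  λ_mlp ‖W_mlp‖²  +  λ_center Σ_ROI ‖μ_xy − c‖² / (S/2)²,

with cross-entropy in nats.  The per-fixation weights default to
(4/7, 2/7, 1/7) — a geometric decay; the source design states only that
earlier fixations weigh more.  λ_mlp = 1e-3 and λ_center = 1e-4 encode
the regularisation asymmetry: re-weighting the classifier is penalised
much harder than moving a fixation toward an informative feature, and
ROI motion itself carries no direct penalty.  MLP biases are not
regularised.  Every convolution filter (one output channel's kernel,
bias excluded) is projected to unit L2 norm after each optimiser step,
so attention is the only mechanism that can amplify feature strength;
the projection preserves filter direction, and a zero-norm filter is
re-initialised with a warning.

Fixations are sampled with the reparameterization trick (mean +
factor · standard normal; the covariance factor is an unconstrained
lower-triangular matrix with log-parameterised diagonal, so it stays
positive definite), which lets the classification loss propagate into
the ROI means and covariances through the masks.  Saccade noise is
added as a non-learnable term.

## Training protocol

Individuals are initialised with 3 large ROIs: spatial means uniform on
the central 80% of the image, spatial SD = image_size/4 (16 px at
64×64), scale mean 1 (middle level) with SD 1.  Optimisation is Adam,
batch size 32, one fixation-sequence sample per image per epoch.  The
network uses a step size of 1e-3; strategy parameters use 5e-2.  The
larger strategy step is a desk-scale calibration: a run here takes a
few hundred optimiser steps rather than the tens of thousands of a
full-scale run, and the gaze strategy must still be able to traverse
tens of pixels within that budget.  Validation accuracy is the top-1
accuracy of the third-fixation prediction, Monte-Carlo averaged over
sampled fixation sequences (1 sample per epoch for the history, 5 for
reported evaluations).  Snapshots of (strategy, network) are stored at
the configured checkpoint epochs.  With fixed seeds and serial
execution the pipeline is reproducible; training runs in float32 (the
autodiff engine's default working precision), so exact histories are
tied to the BLAS in use, while all analysis-side computation is
float64.

## Synthetic stimuli

Stimuli are parametric ellipse-composite faces: a head ellipse, two eye
ellipses, a nose wedge and a mouth bar, rasterised at 64×64 (the
reference resolution; 32×32 and other multiples of 4 are supported and
all geometry scales with resolution).  Identities differ in feature
geometry — eye height/separation/size, nose apex and width, mouth
position and width — and in region gray levels; exemplars of an
identity add a sub-pixel whole-face translation (±1 px at the 64-px
scale), small intensity jitter (SD 0.02) and pixel noise (SD 0.03),
then clip to [0, 1].  The calibration keeps identity-diagnostic
information primarily geometric and concentrated at the eye/nose/mouth
loci: within-identity variation is deliberately smaller than
between-identity differences, which a raw-pixel nearest-centroid
baseline verifies (every 2-identity draw is separable; at 10 identities
the baseline clears chance comfortably).  The 90/10 train/validation
split is stratified per identity (≥1 validation exemplar, every
identity in training).

What the generator does *not* emulate: pose, illumination, expression,
occlusion, alignment error, or the long-tailed exemplar counts of
photographic datasets.  Passing results on these stimuli show that the
learning dynamics and the analysis stack behave as designed, not that
the model attains photographic face-recognition performance.

## EMHMM analysis

Per-individual HMMs are fitted by variational Bayes with conjugate
priors: symmetric Dirichlet (concentration 1) on the prior and each
transition row, Normal–Wishart on emissions (mean prior at the data
mean with covariance from the data scatter, ν₀ = d + 1, β₀ = 0.01).
The E-step runs a scaled forward–backward pass under the usual
expected-log parameters; the M-step updates the conjugate posteriors;
the lower bound is the forward normaliser sum minus the Dirichlet and
Normal–Wishart KL terms and is used as the model-selection score (the
standard VB surrogate for the data log-likelihood).  For each state
count in the preset range (1–6 by default) the fit is restarted many
times (100 by default) from data-seeded initialisations; restarts are
seeded per (K, restart) so enlarging the restart budget strictly
extends the search.  States with negligible posterior occupancy are
pruned, so the effective ROI count can be smaller than the nominal one.
Degenerate data (no variability) short-circuits to a single-ROI model
with a warning.  Reported parameters are posterior means, with emission
covariance (E[Λ])⁻¹ = (νW)⁻¹.

Clustering uses the virtual-sample approximation to hierarchical EM:
each input HMM is represented by sequences sampled from it (the sample
seed derives from the master seed and the HMM's own parameters, so
results are invariant to input order), and hard EM alternates between
refitting one representative HMM per cluster on its members' virtual
samples and reassigning each individual to the representative that
explains its samples best; the best of many restarts by total
log-likelihood wins.  Representative HMMs use the median state count of
the inputs, halves rounded up.  For simulator cohorts clustering runs
in the full (x, y, s) emission space with the saccade-noise variance
folded into the spatial emissions; human fixation CSVs are analysed in
(x, y).

The AB pattern scale is (A − B)/(|A| + |B|), where A and B are an
individual's *mean per-sequence* log-likelihoods under the two
representatives (per-sequence means keep the scale free of the trial
count).  In experiment reports pattern A is oriented as the cluster
whose representative sits higher on the face (smaller mean y) — the
eyes-focused analogue — a geometric rule that cannot bias the
accuracy comparisons.

Overall entropy of a strategy over a T = 3 fixation sequence is

    H = H(Z₁) + Σ_{t=2..T} E[H(Z_t | Z_{t−1})]
      + Σ_{t=1..T} Σ_z P(Z_t = z) · ½ ln((2πe)^d |Σ_z|),

in nats, with state marginals from powers of the transition matrix.  A
per-fixation-normalised variant (total/T) is also reported, since
published human-scale values appear to follow a different normalisation
convention; no numerical reproduction of human entropy means is
claimed.  Deterministic chains contribute zero discrete entropy, so the
closed form 3·ln(2πe σ²) for isotropic 2-D emissions anchors the
implementation.

## The cohort experiment and its scale

The experiment trains a cohort of individuals (same stimuli, different
seeds), then at an early ("partially trained") and a late ("well
trained") checkpoint: simulates fixation sequences per individual,
clusters the strategies into two patterns, computes AB scale and
entropy, evaluates accuracy, and fits the accuracy-vs-scale and
accuracy-vs-entropy regressions plus the between-pattern t-test.

Two profiles ship with the package.  `scaled_reference_config`: 10
identities × 20 exemplars at 32×32, 16 individuals, 150 epochs with
checkpoints {30, 150}, 10 replicate seeds.  `fast_experiment_config`
(used by the test suite): 8 identities × 12 exemplars at 32×32, 12
individuals, 40 epochs with checkpoints {8, 40}, 5 replicates — sizes
chosen so a replicated experiment completes in minutes on one CPU.
Both keep the early checkpoint at 20% of training.  The replicated
summary reports two stochastic properties: the fraction of replicates
with a negative entropy–accuracy correlation at the early checkpoint,
and the fraction in which mean entropy falls from the early to the late
checkpoint.  With a dozen individuals per replicate the per-replicate
correlation carries substantial sampling noise; the package asserts the
sign pattern across replicates, not effect sizes.

## Numerical choices and degenerate inputs

* Autodiff runs in float32 (bandwidth-bound training); analysis code is
  float64.  The soft scale assignment and the softmax cross-entropy are
  max-stabilised.
* Element-wise maximum routes gradients to the larger argument; ties go
  to the earlier fixation.
* Forward log-likelihoods use log-sum-exp; they match exhaustive path
  enumeration to 1e-10 relative on all small models and hmmlearn's
  forward scores on reference fixtures.
* Power calculators scan the sample size against the exact non-central
  F / t distributions; the regression scan starts at the minimum
  fitting size N = k + 2.
* Degenerate cases are first-class: empty validation splits, identical
  fixation data, zero-norm filters, singular covariances, zero pooled
  variance, and missing checkpoints all raise or warn explicitly
  rather than propagating garbage.

## Known limitations

* The perceptual pathway is trained by a from-scratch numpy autodiff
  engine; it is exact but not fast, which is why the shipped experiment
  profiles are desk-scale.  Results at these scales demonstrate the
  qualitative phenomena (routine formation, entropy concentration,
  consistency-before-pattern), not published effect sizes.
* Hard-assignment virtual-sample clustering approximates full
  variational hierarchical EM; with well-separated patterns (the regime
  tested) the two agree, but soft posterior assignment is not
  implemented.
* Fixation durations, stochastic transitions, switching HMMs and
  bottom-up saliency are out of scope by design.
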