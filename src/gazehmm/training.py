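"""Joint training of a gaze strategy and a perceptual network.

One *simulated individual* is a (GazeStrategy, PerceptionNet) pair
trained end-to-end on a labelled stimulus set: per image the strategy
samples a reparameterized fixation sequence, the masked image pyramid
is encoded by the CNN, the VSTM accumulates features across fixations,
and the shared MLP predicts the identity after every fixation.  The
weighted multi-task cross-entropy plus regularisers is minimised with
Adam; gradients reach the ROI means and covariance factors through the
attention masks because fixations are expressed as mean + factor *
standard-normal (reparameterization trick).  Saccade noise is added as
non-learnable noise both during training and evaluation.

A cohort repeats this from different random initialisations; the
individuals differ only in seed.  Strategy parameters use a larger
Adam step than the network: a gaze strategy must traverse tens of
pixels within a training run, and at desk scale (few hundred optimiser
steps) the conventional 1e-3 step would leave the ROIs essentially
where they were initialised.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .faces import StimulusSet, build_pyramid
from .gaze import (
    GazeStrategy,
    ROI,
    SACCADE_NOISE_SD,
    SCALE_TEMPERATURE,
    attention_mask_tensor,
    center_bias_penalty_tensor,
    sample_fixation_sequence,
    scale_weights,
    scale_weights_tensor,
)
from .perception import FIXATION_WEIGHTS, LAMBDA_CENTER, LAMBDA_MLP, PerceptionNet, update_vstm

__all__ = [
    "TrainConfig",
    "SimulatedIndividual",
    "Cohort",
    "initialize_individual",
    "train_individual",
    "evaluate_accuracy",
    "run_cohort",
]

N_FIXATIONS = 3


@dataclasses.dataclass
class TrainConfig:
    """Hyper-parameters of one training run."""

    n_identities: int = 100
    image_size: int = 64
    epochs: int = 500
    checkpoint_epochs: tuple = (100, 500)
    learning_rate: float = 1e-3
    strategy_learning_rate: float = 5e-2
    batch_size: int = 32
    fixation_weights: tuple = FIXATION_WEIGHTS
    lambda_mlp: float = LAMBDA_MLP
    lambda_center: float = LAMBDA_CENTER
    init_roi_spatial_sd: float | None = None  # default: image_size / 4 ("large" ROIs)
    scale_temperature: float = SCALE_TEMPERATURE
    saccade_noise_sd: float = SACCADE_NOISE_SD
    n_repeats_eval: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.init_roi_spatial_sd is None:
            self.init_roi_spatial_sd = self.image_size / 4.0
        if self.epochs < (max(self.checkpoint_epochs) if self.checkpoint_epochs else 0):
            raise ValueError("epochs must cover every checkpoint epoch")
        if self.learning_rate <= 0 or self.strategy_learning_rate <= 0:
            raise ValueError("learning rates must be positive")
        w = np.asarray(self.fixation_weights)
        if np.any(w <= 0) or np.any(np.diff(w) >= 0):
            raise ValueError("fixation weights must be positive and strictly decreasing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["checkpoint_epochs"] = list(self.checkpoint_epochs)
        d["fixation_weights"] = list(self.fixation_weights)
        return d


@dataclasses.dataclass
class SimulatedIndividual:
    """One simulated individual: trainable strategy parameters + network."""

    seed: int
    config: TrainConfig
    net: PerceptionNet
    roi_means: list  # of (3,) Tensors (x, y, s)
    roi_cov_params: list  # of (6,) Tensors (log-diag + lower-triangular)
    history: list = dataclasses.field(default_factory=list)  # per-epoch dicts
    checkpoints: dict = dataclasses.field(default_factory=dict)  # epoch -> snapshot
    epochs_trained: int = 0

    def strategy(self) -> GazeStrategy:
        """Current strategy as a plain (non-trainable) GazeStrategy."""
        rois = []
        for mu, cp in zip(self.roi_means, self.roi_cov_params):
            L = ad.build_tril(cp).data
            rois.append(ROI(mean=mu.data.copy(), covariance=L @ L.T))
        return GazeStrategy(
            rois=rois,
            saccade_noise_sd=self.config.saccade_noise_sd,
            image_size=self.config.image_size,
        )

    def strategy_parameters(self) -> list:
        return list(self.roi_means) + list(self.roi_cov_params)

    def snapshot(self) -> dict:
        return dict(
            strategy=self.strategy().to_dict(),
            net={k: v.copy() for k, v in self.net.state_arrays().items()},
        )

    def checkpoint_strategy(self, epoch: int) -> GazeStrategy:
        return GazeStrategy.from_dict(self.checkpoints[epoch]["strategy"])

    def checkpoint_net(self, epoch: int) -> PerceptionNet:
        net = PerceptionNet(
            image_size=self.config.image_size,
            n_classes=self.net.n_classes,
            rng=np.random.default_rng(0),
        )
        return net.load_state_arrays(self.checkpoints[epoch]["net"])


def initialize_individual(config: TrainConfig, seed: int) -> SimulatedIndividual:
    """Three large ROIs at random locations in the central 80% of the image.

    Spatial means are uniform over the central 80%, spatial SD is
    ``config.init_roi_spatial_sd``; the scale coordinate starts at the
    middle level (mean 1, SD 1).  Network weights are drawn from the
    same seed and unit-norm projected.
    """
    rng = np.random.default_rng(seed)
    S = config.image_size
    lo, hi = 0.1 * S, 0.9 * S
    roi_means, roi_cov_params = [], []
    for _ in range(N_FIXATIONS):
        x, y = rng.uniform(lo, hi, size=2)
        roi_means.append(Tensor(np.array([x, y, 1.0]), requires_grad=True))
        cp = np.zeros(6)
        cp[0] = cp[1] = np.log(config.init_roi_spatial_sd)
        cp[2] = np.log(1.0)  # scale-coordinate SD 1
        roi_cov_params.append(Tensor(cp, requires_grad=True))
    net = PerceptionNet(image_size=S, n_classes=config.n_identities, rng=rng)
    return SimulatedIndividual(
        seed=seed, config=config, net=net, roi_means=roi_means, roi_cov_params=roi_cov_params
    )


def stack_pyramids(images: list) -> list:
    """Precompute pyramids for a list of images: 3 arrays (N, side, side, 1)."""
    pyrs = [build_pyramid(img).levels for img in images]
    return [np.stack([p[l] for p in pyrs])[..., None] for l in range(3)]


def _forward_loss(ind: SimulatedIndividual, level_batches: list, labels: np.ndarray, rng) -> tuple:
    """Differentiable forward pass for one mini-batch.

    Returns (total loss Tensor, per-fixation cross-entropy values).
    """
    cfg = ind.config
    B = labels.shape[0]
    S = cfg.image_size
    w = np.asarray(cfg.fixation_weights, dtype=float)
    # the chain is deterministic, so all T fixations can be sampled up front
    # and pushed through the (shared) conv stacks and MLP as one batch of 3B
    masked_by_level = [[] for _ in level_batches]
    for t in range(N_FIXATIONS):
        mu, cp = ind.roi_means[t], ind.roi_cov_params[t]
        L = ad.build_tril(cp)
        eps = rng.standard_normal((B, 3))
        f = mu.reshape(1, 3) + Tensor(eps) @ L.T
        delta = cfg.saccade_noise_sd * rng.standard_normal((B, 2))
        loc = (f[:, 0:2] + Tensor(delta)).clip(0.0, S - 1.0)
        weights = scale_weights_tensor(f[:, 2:3], cfg.scale_temperature)
        for lvl, batch in enumerate(level_batches):
            mask = attention_mask_tensor(loc, weights[:, lvl : lvl + 1], lvl, S)
            masked_by_level[lvl].append(Tensor(batch) * mask)
    stacked = [ad.concat(per_fix, axis=0) for per_fix in masked_by_level]
    feats = ind.net.extract_features(stacked)  # per level: (3B, h, w, c)
    vstm_per_t = []  # running element-wise max over fixations, per level
    vstm = None
    for t in range(N_FIXATIONS):
        step_feats = [fl[t * B : (t + 1) * B] for fl in feats]
        vstm = update_vstm(vstm, step_feats)
        vstm_per_t.append(vstm)
    flat = ad.concat(
        [ad.concat([v.reshape(B, -1) for v in vs], axis=1) for vs in vstm_per_t], axis=0
    )
    logits = ind.net.classify_flat_logits(flat)  # (3B, C)
    ces, loss = [], None
    for t in range(N_FIXATIONS):
        ce = ad.softmax_cross_entropy(logits[t * B : (t + 1) * B], labels)
        ces.append(float(ce.data))
        loss = ce * w[t] if loss is None else loss + ce * w[t]
    loss = loss + ind.net.mlp_l2() * cfg.lambda_mlp
    loss = loss + center_bias_penalty_tensor(ind.roi_means, S) * cfg.lambda_center
    return loss, ces


def train_individual(
    ind: SimulatedIndividual, stimuli: StimulusSet, config: TrainConfig | None = None
) -> SimulatedIndividual:
    """Train one individual in place; returns it for chaining.

    Per epoch: shuffled mini-batches, one fixation-sequence sample per
    image, Adam steps (separate step sizes for network and strategy),
    unit-norm projection after every step, then validation accuracy.
    Snapshots are stored at the configured checkpoint epochs.
    """
    cfg = config or ind.config
    if stimuli.n_classes > cfg.n_identities:
        raise ValueError("stimulus set has more classes than the configured n_identities")
    rng = np.random.default_rng(np.random.SeedSequence([int(ind.seed), 7]))
    train_imgs, train_labels = stimuli.subset("train")
    levels = stack_pyramids(train_imgs)
    val_pyr = stack_pyramids(stimuli.subset("val")[0])
    val_labels = stimuli.subset("val")[1]
    opt_net = Adam(ind.net.parameters(), lr=cfg.learning_rate)
    opt_strategy = Adam(ind.strategy_parameters(), lr=cfg.strategy_learning_rate)
    n = len(train_imgs)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_levels = [lv[idx] for lv in levels]
            loss, _ = _forward_loss(ind, batch_levels, train_labels[idx], rng)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, seed {ind.seed}"
                )
            opt_net.zero_grad()
            opt_strategy.zero_grad()
            loss.backward()
            opt_net.step()
            opt_strategy.step()
            ind.net.enforce_unit_norm()
            epoch_losses.append(float(loss.data))
        val_acc = _accuracy_np(ind.net, ind.strategy(), val_pyr, val_labels, rng, n_repeats=1)
        ind.history.append(dict(epoch=epoch, train_loss=float(np.mean(epoch_losses)), val_accuracy=val_acc))
        ind.epochs_trained = epoch
        if epoch in set(cfg.checkpoint_epochs):
            ind.checkpoints[epoch] = ind.snapshot()
    return ind


def _accuracy_np(net, strategy, level_batches, labels, rng, n_repeats=5, temperature=SCALE_TEMPERATURE):
    """Monte-Carlo top-1 accuracy of the 3rd-fixation prediction (numpy path)."""
    N = labels.shape[0]
    S = strategy.image_size
    hmm_chol = [np.linalg.cholesky(roi.covariance) for roi in strategy.rois]
    correct = 0.0
    for _ in range(n_repeats):
        vstm = None
        for t, roi in enumerate(strategy.rois):
            eps = rng.standard_normal((N, 3))
            f = roi.mean[None, :] + eps @ hmm_chol[t].T
            f[:, :2] += strategy.saccade_noise_sd * rng.standard_normal((N, 2))
            loc = np.clip(f[:, :2], 0, S - 1)
            wts = np.stack([scale_weights(s, temperature) for s in f[:, 2]])
            masked = []
            for lvl, batch in enumerate(level_batches):
                side = batch.shape[1]
                Y, X = np.mgrid[0:side, 0:side].astype(float)
                lx = loc[:, 0, None, None] / 2**lvl
                ly = loc[:, 1, None, None] / 2**lvl
                d2 = (X[None] - lx) ** 2 + (Y[None] - ly) ** 2
                mask = wts[:, lvl, None, None] * np.exp(-d2 / (2 * 4.0**2))
                masked.append(batch * mask[..., None])
            feats = net.extract_features_np(masked)
            vstm = feats if vstm is None else [np.maximum(v, f2) for v, f2 in zip(vstm, feats)]
        probs = net.classify(vstm)
        correct += float(np.mean(probs.argmax(axis=1) == labels))
    return correct / n_repeats


def evaluate_accuracy(
    individual_or_pair,
    stimuli: StimulusSet,
    which: str = "val",
    n_repeats: int | None = None,
    seed: int = 0,
) -> float:
    """Top-1 accuracy of the prediction after the final fixation.

    Fixations are sampled with saccade noise; ``n_repeats`` Monte-Carlo
    samples per image are averaged (default from the config, 5).
    Accepts a SimulatedIndividual or a (net, strategy) pair.
    """
    if isinstance(individual_or_pair, SimulatedIndividual):
        net = individual_or_pair.net
        strategy = individual_or_pair.strategy()
        if n_repeats is None:
            n_repeats = individual_or_pair.config.n_repeats_eval
    else:
        net, strategy = individual_or_pair
        if n_repeats is None:
            n_repeats = 5
    imgs, labels = stimuli.subset(which)
    if len(imgs) == 0:
        raise ValueError(f"empty split {which!r}")
    levels = stack_pyramids(imgs)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    return _accuracy_np(net, strategy, levels, labels, rng, n_repeats=n_repeats)


def simulate_individual_fixations(
    strategy: GazeStrategy, n_trials: int, seed: int = 0, temperature: float = SCALE_TEMPERATURE
) -> list:
    """Sample ``n_trials`` fixation sequences from a strategy."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    return [
        sample_fixation_sequence(strategy, rng, trial_id=i, temperature=temperature)
        for i in range(n_trials)
    ]


@dataclasses.dataclass
class Cohort:
    individuals: list  # of SimulatedIndividual (or None on failure)
    stimuli: StimulusSet
    config: TrainConfig
    statuses: list  # "ok" | error message per individual

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def run_cohort(
    config: TrainConfig,
    n_individuals: int = 80,
    stimuli: StimulusSet | None = None,
    seed0: int | None = None,
    out_dir=None,
    progress: bool = False,
) -> Cohort:
    """Train ``n_individuals`` with seeds seed0 .. seed0+n-1 serially.

    If ``out_dir`` is given, each finished individual is written to
    disk and an interrupted run resumes by loading the completed ones;
    with fixed seeds and serial execution a resumed run reproduces the
    uninterrupted result.
    """
    from .faces import generate_identity_prototypes, render_stimulus_set

    if stimuli is None:
        protos = generate_identity_prototypes(config.n_identities, config.seed, config.image_size)
        stimuli = render_stimulus_set(protos, exemplars_per_identity=20, rng_seed=config.seed + 1)
    if seed0 is None:
        seed0 = config.seed + 100
    out_dir = pathlib.Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    individuals, statuses = [], []
    for i in range(n_individuals):
        seed = seed0 + i
        path = out_dir / f"individual_{i:03d}.npz" if out_dir is not None else None
        if path is not None and path.exists():
            individuals.append(load_individual(path, config))
            statuses.append("ok")
            continue
        try:
            ind = initialize_individual(config, seed)
            train_individual(ind, stimuli, config)
            individuals.append(ind)
            statuses.append("ok")
            if path is not None:
                save_individual(ind, path)
        except Exception as exc:  # keep the cohort usable on partial failure
            warnings.warn(f"individual {i} (seed {seed}) failed: {exc}")
            individuals.append(None)
            statuses.append(str(exc))
        if progress:
            print(f"individual {i + 1}/{n_individuals} done", flush=True)
    return Cohort(individuals=individuals, stimuli=stimuli, config=config, statuses=statuses)


# ---------------------------------------------------------------------------
# checkpoint archive: compressed npz of named arrays + JSON manifest entries
# ---------------------------------------------------------------------------

def save_individual(ind: SimulatedIndividual, path) -> None:
    arrays = {f"net_{k}": v for k, v in ind.net.state_arrays().items()}
    for t in range(N_FIXATIONS):
        arrays[f"roi_mean_{t}"] = ind.roi_means[t].data
        arrays[f"roi_cov_params_{t}"] = ind.roi_cov_params[t].data
    for epoch, snap in ind.checkpoints.items():
        for k, v in snap["net"].items():
            arrays[f"ckpt{epoch}_net_{k}"] = v
        arrays[f"ckpt{epoch}_strategy_json"] = np.frombuffer(
            json.dumps(snap["strategy"]).encode(), dtype=np.uint8
        )
    manifest = dict(
        seed=int(ind.seed),
        epochs_trained=int(ind.epochs_trained),
        config=ind.config.to_dict(),
        history=ind.history,
        checkpoint_epochs=sorted(int(e) for e in ind.checkpoints),
    )
    arrays["manifest_json"] = np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)
    path = pathlib.Path(path)
    tmp = path.with_suffix(".tmp.npz")
    np.savez_compressed(tmp, **arrays)
    tmp.replace(path)


def load_individual(path, config: TrainConfig | None = None) -> SimulatedIndividual:
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    manifest = json.loads(bytes(arrays.pop("manifest_json")).decode())
    if config is None:
        cd = manifest["config"]
        cd["checkpoint_epochs"] = tuple(cd["checkpoint_epochs"])
        cd["fixation_weights"] = tuple(cd["fixation_weights"])
        config = TrainConfig(**cd)
    ind = initialize_individual(config, manifest["seed"])
    ind.net.load_state_arrays({k[len("net_") :]: v for k, v in arrays.items() if k.startswith("net_")})
    for t in range(N_FIXATIONS):
        ind.roi_means[t].data = np.array(arrays[f"roi_mean_{t}"], dtype=float)
        ind.roi_cov_params[t].data = np.array(arrays[f"roi_cov_params_{t}"], dtype=float)
    ind.history = manifest["history"]
    ind.epochs_trained = manifest["epochs_trained"]
    for epoch in manifest["checkpoint_epochs"]:
        net_arrays = {
            k[len(f"ckpt{epoch}_net_") :]: v
            for k, v in arrays.items()
            if k.startswith(f"ckpt{epoch}_net_")
        }
        strategy = json.loads(bytes(arrays[f"ckpt{epoch}_strategy_json"]).decode())
        ind.checkpoints[epoch] = dict(strategy=strategy, net=net_arrays)
    return ind
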