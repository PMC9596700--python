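"""The generative eye-movement-strategy model.

An individual's strategy is a tiny hidden Markov model whose states are
regions of interest (ROIs): Gaussians over fixation location (x, y, in
pixels) and a continuous spatial-frequency scale coordinate s.  In the
reference configuration the chain is deterministic (prior (1,0,0),
transitions 1->2->3), so a trial is exactly T=3 fixations, one per ROI.
Fixations are the ROI mean plus emission noise plus isotropic saccade
(motor) noise of SD 3 px (0.375 degrees at 8 px/degree).

The scale coordinate selects among three pyramid levels (32, 16 and 8
cycles/face, i.e. attention windows of 8, 16 and 32 px) through soft
Gaussian responsibilities, which keeps the selection differentiable; a
hard selection is the argmax weight.  Each fixation yields one Gaussian
attention mask per pyramid level, centred at the (down-scaled) fixation
location, whose peak equals the level's scale weight; the mask SD is
half the attention window at full resolution, which works out to 4 px
in every level's own pixel grid.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .autodiff import Tensor, concat
from .faces import ImagePyramid

__all__ = [
    "ROI",
    "GazeStrategy",
    "Fixation",
    "FixationSequence",
    "AttentionMaskSet",
    "scale_weights",
    "attention_masks",
    "apply_masks",
    "center_bias_penalty",
    "sample_fixation_sequence",
]

#: pixels per degree of visual angle (3 px saccade noise = 0.375 deg)
PX_PER_DEGREE = 8.0
#: saccade (motor) noise SD in pixels, reference configuration
SACCADE_NOISE_SD = 3.0
#: attention-mask SD in level-local pixels (= half window / 2**level)
MASK_SIGMA = 4.0
#: default temperature of the soft scale assignment
SCALE_TEMPERATURE = 0.5
#: fixations per trial in the reference configuration
N_FIXATIONS = 3
#: cycles/face of pyramid levels 0, 1, 2
LEVEL_CYCLES = (32, 16, 8)
#: attention window size (px, full resolution) of pyramid levels 0, 1, 2
LEVEL_WINDOW_PX = (8, 16, 32)


@dataclasses.dataclass
class ROI:
    """A region of interest: Gaussian over (x, y, s)."""

    mean: np.ndarray  # (3,): x px, y px, scale coordinate
    covariance: np.ndarray  # (3, 3) positive definite

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (3,) or not np.all(np.isfinite(self.mean)):
            raise ValueError("ROI mean must be a finite 3-vector")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("ROI covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise ValueError("ROI covariance must be positive definite")


@dataclasses.dataclass
class GazeStrategy:
    """An individual's HMM over fixation location and scale."""

    rois: list  # of ROI, ordered
    prior: np.ndarray = None
    transition: np.ndarray = None
    saccade_noise_sd: float = SACCADE_NOISE_SD
    image_size: int = 64

    def __post_init__(self):
        k = len(self.rois)
        if self.prior is None:  # deterministic chain 1 -> 2 -> ... -> k
            self.prior = np.eye(k)[0]
        if self.transition is None:
            self.transition = np.eye(k, k=1)
            self.transition[-1, -1] = 1.0
        self.prior = np.asarray(self.prior, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("prior must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return dict(
            rois=[dict(mean=r.mean.tolist(), cov=r.covariance.tolist()) for r in self.rois],
            prior=self.prior.tolist(),
            transition=self.transition.tolist(),
            saccade_noise_sd=self.saccade_noise_sd,
            image_size=self.image_size,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "GazeStrategy":
        return cls(
            rois=[ROI(np.array(r["mean"]), np.array(r["cov"])) for r in d["rois"]],
            prior=np.array(d["prior"]),
            transition=np.array(d["transition"]),
            saccade_noise_sd=float(d["saccade_noise_sd"]),
            image_size=int(d["image_size"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GazeStrategy":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def effective_hmm(self, include_scale: bool = True) -> dict:
        """HMM parameters of the *observed* fixation process.

        Saccade noise convolves into the spatial part of each emission,
        so the observed emission covariance is the ROI covariance plus
        ``saccade_noise_sd**2`` on the two spatial diagonal entries.
        """
        d = 3 if include_scale else 2
        means, covs = [], []
        for roi in self.rois:
            m = roi.mean[:d].copy()
            c = roi.covariance[:d, :d].copy()
            c[0, 0] += self.saccade_noise_sd**2
            c[1, 1] += self.saccade_noise_sd**2
            means.append(m)
            covs.append(c)
        return dict(
            prior=self.prior.copy(),
            transition=self.transition.copy(),
            means=np.array(means),
            covariances=np.array(covs),
        )


@dataclasses.dataclass
class Fixation:
    """One fixation: continuous location plus soft weights over SF levels."""

    location: np.ndarray  # (2,): x, y in px
    scale_weights: np.ndarray  # (3,), on the simplex
    scale: float = np.nan  # the underlying continuous scale coordinate

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float)
        self.scale_weights = np.asarray(self.scale_weights, dtype=float)
        if np.any(self.scale_weights < 0) or not np.isclose(self.scale_weights.sum(), 1.0):
            raise ValueError("scale_weights must be a probability vector")


@dataclasses.dataclass
class FixationSequence:
    fixations: list  # of Fixation
    trial_id: int = 0

    def __len__(self):
        return len(self.fixations)

    def locations(self) -> np.ndarray:
        return np.array([f.location for f in self.fixations])

    def as_array(self, include_scale: bool = True) -> np.ndarray:
        """(T, 2) or (T, 3) array of (x, y[, s])."""
        if include_scale:
            return np.array([[*f.location, f.scale] for f in self.fixations])
        return self.locations()


@dataclasses.dataclass
class AttentionMaskSet:
    masks: tuple  # per-level arrays matching the pyramid level shapes


def scale_weights(s: float, temperature: float = SCALE_TEMPERATURE) -> np.ndarray:
    """Soft assignment of a scale coordinate to the 3 pyramid levels.

    weight[l] is proportional to exp(-(s - l)^2 / (2 * temperature^2)),
    l in {0, 1, 2}; level 0 is 32 cycles/face (8-px window), level 2 is
    8 cycles/face (32-px window).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    levels = np.arange(3.0)
    logw = -((s - levels) ** 2) / (2.0 * temperature**2)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def attention_masks(
    fixation: Fixation, pyramid_meta=None, image_size: int = 64
) -> AttentionMaskSet:
    """Per-level Gaussian attention masks for one fixation.

    At level l the mask is ``scale_weights[l] * exp(-||p - loc/2**l||^2
    / (2 * MASK_SIGMA**2))`` over that level's pixel grid: the peak
    value equals the scale weight and the SD corresponds to half the
    attention window at full resolution.  Locations outside the image
    are clipped to the bounds first.
    """
    masks = []
    loc = np.clip(fixation.location, 0, image_size - 1)
    for lvl in range(3):
        side = image_size // (2**lvl)
        Y, X = np.mgrid[0:side, 0:side].astype(float)
        lx, ly = loc / (2**lvl)
        d2 = (X - lx) ** 2 + (Y - ly) ** 2
        masks.append(fixation.scale_weights[lvl] * np.exp(-d2 / (2.0 * MASK_SIGMA**2)))
    return AttentionMaskSet(masks=tuple(masks))


def apply_masks(pyramid: ImagePyramid, masks: AttentionMaskSet) -> tuple:
    """Element-wise product of each pyramid level with its mask."""
    out = []
    for level, mask in zip(pyramid.levels, masks.masks):
        if level.shape != mask.shape:
            raise ValueError(f"shape mismatch: level {level.shape} vs mask {mask.shape}")
        out.append(level * mask)
    return tuple(out)


def center_bias_penalty(strategy, image_size: int | None = None) -> float:
    """Centre-bias regulariser on ROI locations.

    Sum over ROIs of the squared distance of the spatial mean from the
    image centre, normalised by (image_size / 2)**2 so the value is
    comparable across resolutions.
    """
    if image_size is None:
        image_size = strategy.image_size
    c = image_size / 2.0
    total = 0.0
    for roi in strategy.rois:
        total += float((roi.mean[0] - c) ** 2 + (roi.mean[1] - c) ** 2)
    return total / (image_size / 2.0) ** 2


def sample_fixation_sequence(
    strategy: GazeStrategy,
    rng: np.random.Generator,
    trial_id: int = 0,
    temperature: float = SCALE_TEMPERATURE,
    clip_to_image: bool = True,
) -> FixationSequence:
    """Sample one trial of fixations from a strategy.

    The state sequence follows prior/transition (a point mass per step
    for the deterministic chain).  Each fixation is the ROI mean plus
    emission noise (Cholesky of the ROI covariance applied to standard
    normals) plus isotropic saccade noise on the spatial coordinates.
    """
    k = strategy.n_rois
    state = rng.choice(k, p=strategy.prior)
    fixations = []
    for t in range(N_FIXATIONS):
        roi = strategy.rois[state]
        L = np.linalg.cholesky(roi.covariance)
        x = roi.mean + L @ rng.standard_normal(3)
        x[:2] += strategy.saccade_noise_sd * rng.standard_normal(2)
        loc = x[:2]
        if clip_to_image:
            loc = np.clip(loc, 0, strategy.image_size - 1)
        fixations.append(Fixation(location=loc, scale_weights=scale_weights(x[2], temperature), scale=float(x[2])))
        if t < N_FIXATIONS - 1:
            state = rng.choice(k, p=strategy.transition[state])
    return FixationSequence(fixations=fixations, trial_id=trial_id)


# ---------------------------------------------------------------------------
# differentiable (Tensor) counterparts used during joint training
# ---------------------------------------------------------------------------

def scale_weights_tensor(s: Tensor, temperature: float = SCALE_TEMPERATURE) -> Tensor:
    """Soft scale weights for a batch; s has shape (B, 1), output (B, 3).

    Log-weights are shifted by their maximum before exponentiating
    (softmax-style) so the normaliser cannot underflow when the scale
    coordinate drifts far from the level grid.
    """
    from .autodiff import maximum

    inv = 1.0 / (2.0 * temperature**2)
    logs = [((s - float(lvl)) ** 2 * (-inv)) for lvl in range(3)]
    m = maximum(maximum(logs[0], logs[1]), logs[2])
    r = concat([(lw - m).exp() for lw in logs], axis=1)
    return r / r.sum(axis=1, keepdims=True)


def attention_mask_tensor(loc: Tensor, weight_l: Tensor, level: int, image_size: int) -> Tensor:
    """Mask for one pyramid level, batched: (B, side, side, 1).

    ``loc`` is (B, 2) clipped fixation locations at full resolution;
    ``weight_l`` is the (B, 1) scale weight of this level.
    """
    side = image_size // (2**level)
    Y, X = np.mgrid[0:side, 0:side].astype(float)
    Xg = Tensor(X[None, :, :, None])
    Yg = Tensor(Y[None, :, :, None])
    inv_scale = 1.0 / (2**level)
    lx = (loc[:, 0:1] * inv_scale).reshape(-1, 1, 1, 1)
    ly = (loc[:, 1:2] * inv_scale).reshape(-1, 1, 1, 1)
    d2 = (Xg - lx) ** 2 + (Yg - ly) ** 2
    g = (d2 * (-1.0 / (2.0 * MASK_SIGMA**2))).exp()
    return g * weight_l.reshape(-1, 1, 1, 1)


def center_bias_penalty_tensor(roi_means, image_size: int) -> Tensor:
    """Differentiable centre-bias penalty over a list of (3,) mean Tensors."""
    c = image_size / 2.0
    total = None
    for mu in roi_means:
        term = ((mu[0:2] - c) ** 2).sum()
        total = term if total is None else total + term
    return total * (1.0 / (image_size / 2.0) ** 2)
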