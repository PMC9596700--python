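"""The learnable perceptual pathway.

A multi-scale CNN (one small two-layer stack per pyramid level, 3x3
kernels, 8 then 16 channels, valid mode, ReLU) extracts features from
each attention-masked pyramid level.  Features are aggregated across
fixations into a visual short-term memory (VSTM) by element-wise
maximum, so each fixation can only strengthen the remembered evidence.
A shared two-layer MLP (40 hidden units, softmax output) decodes the
VSTM into identity probabilities after every fixation.

Every convolution filter is constrained to unit L2 norm (projected
after each optimiser step): the attention mask is then the only
mechanism that can amplify a feature.  The training loss is a weighted
sum of the per-fixation cross-entropies (earlier fixations weighted
more, so the model identifies with as few fixations as possible) plus
an L2 penalty on the MLP weights and a centre bias on ROI locations.
The penalty asymmetry — MLP weights are regularised much harder than
fixation movement — pushes learning toward moving fixations onto
informative features rather than re-weighting the classifier.

At the reference configuration (64x64 input, 3 levels, 100 classes)
the CNN has 3744 parameters and the MLP 2,902,060.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "PerceptionNet",
    "LossBreakdown",
    "FIXATION_WEIGHTS",
    "update_vstm",
    "multitask_loss",
]

#: default per-fixation loss weights (strictly decreasing, sum to 1)
FIXATION_WEIGHTS = (4 / 7, 2 / 7, 1 / 7)
#: default L2 coefficient on MLP weights (heavier …)
LAMBDA_MLP = 1e-3
#: … than the centre bias on ROI locations
LAMBDA_CENTER = 1e-4


def conv_output_side(side: int, n_layers: int = 2, kernel: int = 3) -> int:
    return side - n_layers * (kernel - 1)


class PerceptionNet:
    """Multi-scale CNN + shared MLP classifier with unit-norm conv filters."""

    def __init__(
        self,
        image_size: int = 64,
        n_classes: int = 100,
        conv_channels: tuple = (8, 16),
        hidden_units: int = 40,
        n_levels: int = 3,
        rng: np.random.Generator | None = None,
    ):
        if rng is None:
            rng = np.random.default_rng(0)
        self.image_size = int(image_size)
        self.n_classes = int(n_classes)
        self.conv_channels = tuple(conv_channels)
        self.hidden_units = int(hidden_units)
        self.n_levels = int(n_levels)
        self.level_sides = tuple(image_size // 2**l for l in range(n_levels))
        for side in self.level_sides:
            if conv_output_side(side) < 1:
                raise ValueError(f"pyramid level of side {side} too small for two 3x3 valid convolutions")
        self.feature_sides = tuple(conv_output_side(s) for s in self.level_sides)
        self.feature_dim = int(sum(s * s for s in self.feature_sides) * conv_channels[1])

        c1, c2 = conv_channels
        self.conv_stacks = []
        for _ in range(n_levels):
            w1 = Tensor(rng.standard_normal((3, 3, 1, c1)), requires_grad=True)
            b1 = Tensor(np.zeros(c1), requires_grad=True)
            w2 = Tensor(rng.standard_normal((3, 3, c1, c2)), requires_grad=True)
            b2 = Tensor(np.zeros(c2), requires_grad=True)
            self.conv_stacks.append((w1, b1, w2, b2))
        glorot_h = np.sqrt(2.0 / (self.feature_dim + hidden_units))
        glorot_o = np.sqrt(2.0 / (hidden_units + n_classes))
        self.w_hidden = Tensor(rng.normal(0, glorot_h, (self.feature_dim, hidden_units)), requires_grad=True)
        self.b_hidden = Tensor(np.zeros(hidden_units), requires_grad=True)
        self.w_out = Tensor(rng.normal(0, glorot_o, (hidden_units, n_classes)), requires_grad=True)
        self.b_out = Tensor(np.zeros(n_classes), requires_grad=True)
        self.enforce_unit_norm()

    # -- parameter bookkeeping ------------------------------------------
    def conv_parameters(self) -> list:
        return [t for stack in self.conv_stacks for t in stack]

    def mlp_parameters(self) -> list:
        return [self.w_hidden, self.b_hidden, self.w_out, self.b_out]

    def parameters(self) -> list:
        return self.conv_parameters() + self.mlp_parameters()

    def count_parameters(self) -> tuple:
        """(conv_count, mlp_count), biases included."""
        conv = sum(t.data.size for t in self.conv_parameters())
        mlp = sum(t.data.size for t in self.mlp_parameters())
        return conv, mlp

    def enforce_unit_norm(self) -> "PerceptionNet":
        """Project every conv filter onto the unit L2 sphere (biases untouched).

        A filter is one output channel's (3, 3, in_channels) kernel.  A
        zero-norm filter cannot be projected; it is re-initialised with
        a warning.
        """
        rng = np.random.default_rng(12345)
        for w1, _, w2, _ in self.conv_stacks:
            for w in (w1, w2):
                flat = w.data.reshape(-1, w.data.shape[-1])  # (9*cin, cout)
                norms = np.linalg.norm(flat, axis=0)
                dead = norms < 1e-12
                if np.any(dead):
                    warnings.warn("zero-norm convolution filter re-initialised")
                    flat[:, dead] = rng.standard_normal((flat.shape[0], int(dead.sum())))
                    norms = np.linalg.norm(flat, axis=0)
                w.data = (flat / norms).reshape(w.data.shape)
        return self

    # -- differentiable forward (training path) -------------------------
    def extract_features(self, masked_levels: list) -> list:
        """Per-level conv features; inputs are (B, side, side, 1) Tensors."""
        feats = []
        for (w1, b1, w2, b2), x in zip(self.conv_stacks, masked_levels):
            h = ad.conv2d_valid(x, w1, b1).relu()
            feats.append(ad.conv2d_valid(h, w2, b2).relu())
        return feats

    def classify_logits(self, vstm_levels: list) -> Tensor:
        """Flatten + concat the VSTM levels and run the MLP; (B, C) logits."""
        flat = ad.concat([v.reshape(v.shape[0], -1) for v in vstm_levels], axis=1)
        return self.classify_flat_logits(flat)

    def classify_flat_logits(self, flat: Tensor) -> Tensor:
        """MLP logits from an already-flattened (B, feature_dim) Tensor."""
        h = (flat @ self.w_hidden + self.b_hidden).relu()
        return h @ self.w_out + self.b_out

    def mlp_l2(self) -> Tensor:
        """Sum of squared MLP weights (biases not regularised)."""
        return self.w_hidden.sumsq() + self.w_out.sumsq()

    # -- plain numpy forward (inference path) ----------------------------
    def extract_features_np(self, masked_levels: list) -> list:
        feats = []
        for (w1, b1, w2, b2), x in zip(self.conv_stacks, masked_levels):
            h = np.maximum(_conv_np(x, w1.data, b1.data), 0.0)
            feats.append(np.maximum(_conv_np(h, w2.data, b2.data), 0.0))
        return feats

    def classify(self, vstm_levels: list) -> np.ndarray:
        """Identity probabilities from a (possibly batched) numpy VSTM."""
        flat = np.concatenate([v.reshape(v.shape[0], -1) for v in vstm_levels], axis=1)
        if flat.shape[1] != self.feature_dim:
            raise ValueError(f"VSTM dimension {flat.shape[1]} != configured {self.feature_dim}")
        h = np.maximum(flat @ self.w_hidden.data + self.b_hidden.data, 0.0)
        z = h @ self.w_out.data + self.b_out.data
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    # -- serialisation ----------------------------------------------------
    def state_arrays(self) -> dict:
        out = {}
        for l, (w1, b1, w2, b2) in enumerate(self.conv_stacks):
            out[f"conv{l}_w1"], out[f"conv{l}_b1"] = w1.data, b1.data
            out[f"conv{l}_w2"], out[f"conv{l}_b2"] = w2.data, b2.data
        out["w_hidden"], out["b_hidden"] = self.w_hidden.data, self.b_hidden.data
        out["w_out"], out["b_out"] = self.w_out.data, self.b_out.data
        return out

    def load_state_arrays(self, arrays: dict) -> "PerceptionNet":
        for l, (w1, b1, w2, b2) in enumerate(self.conv_stacks):
            w1.data = np.array(arrays[f"conv{l}_w1"], dtype=float)
            b1.data = np.array(arrays[f"conv{l}_b1"], dtype=float)
            w2.data = np.array(arrays[f"conv{l}_w2"], dtype=float)
            b2.data = np.array(arrays[f"conv{l}_b2"], dtype=float)
        self.w_hidden.data = np.array(arrays["w_hidden"], dtype=float)
        self.b_hidden.data = np.array(arrays["b_hidden"], dtype=float)
        self.w_out.data = np.array(arrays["w_out"], dtype=float)
        self.b_out.data = np.array(arrays["b_out"], dtype=float)
        return self


def _conv_np(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid-mode channels-last convolution, numpy inference twin of conv2d_valid."""
    kh, kw = w.shape[:2]
    B, H, W, _ = x.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    out = np.broadcast_to(b, (B, Ho, Wo, b.shape[0])).copy()
    for u in range(kh):
        for v in range(kw):
            out += x[:, u : u + Ho, v : v + Wo, :] @ w[u, v]
    return out


def update_vstm(vstm, features):
    """Element-wise maximum update of the VSTM; first update initialises it.

    Works on single arrays/Tensors or per-level lists of them.
    """
    if vstm is None:
        return features
    if isinstance(vstm, (list, tuple)):
        if len(vstm) != len(features):
            raise ValueError("VSTM and feature level counts differ")
        return [update_vstm(v, f) for v, f in zip(vstm, features)]
    if isinstance(vstm, Tensor) or isinstance(features, Tensor):
        return ad.maximum(vstm, features)
    vstm = np.asarray(vstm, dtype=float)
    features = np.asarray(features, dtype=float)
    if vstm.shape != features.shape:
        raise ValueError(f"shape mismatch {vstm.shape} vs {features.shape}")
    return np.maximum(vstm, features)


@dataclasses.dataclass
class LossBreakdown:
    per_fixation_ce: np.ndarray  # (T,)
    fixation_weights: np.ndarray  # (T,), strictly decreasing, sums to 1
    reg_mlp: float
    reg_center: float
    lambda_mlp: float
    lambda_center: float

    @property
    def weighted_ce(self) -> float:
        return float(self.fixation_weights @ self.per_fixation_ce)

    @property
    def total(self) -> float:
        return self.weighted_ce + self.lambda_mlp * self.reg_mlp + self.lambda_center * self.reg_center


def multitask_loss(
    per_fixation_probs,
    label: int,
    fixation_weights=FIXATION_WEIGHTS,
    reg_mlp: float = 0.0,
    reg_center: float = 0.0,
    lambda_mlp: float = LAMBDA_MLP,
    lambda_center: float = LAMBDA_CENTER,
) -> LossBreakdown:
    """Weighted multi-task cross-entropy (natural log) over T predictions."""
    w = np.asarray(fixation_weights, dtype=float)
    if np.any(w <= 0) or np.any(np.diff(w) >= 0):
        raise ValueError("fixation weights must be positive and strictly decreasing")
    ce = np.array([-np.log(np.asarray(p, dtype=float)[label]) for p in per_fixation_probs])
    return LossBreakdown(
        per_fixation_ce=ce,
        fixation_weights=w,
        reg_mlp=float(reg_mlp),
        reg_center=float(reg_center),
        lambda_mlp=float(lambda_mlp),
        lambda_center=float(lambda_center),
    )
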