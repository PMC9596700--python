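"""Synthetic face-like stimuli and spatial-frequency image pyramids.

Face recognition with diagnostic features at the eyes, nose and mouth is
what the gaze model learns from.  Photorealism is irrelevant to the
claims being modelled — what matters is that identities differ in
feature geometry and intensity at those loci, that exemplars of an
identity vary, and that the stimuli come with a stratified 90/10
train/validation split.  The generator therefore draws parametric
ellipse-composite faces (head ellipse, two eye ellipses, a nose wedge,
a mouth bar) whose geometry is jittered per identity around a canonical
layout.

A loader for a directory of real grayscale PNG images with a manifest
CSV is provided as well, so the same pipeline runs on externally
supplied face datasets.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "IdentityPrototype",
    "StimulusSet",
    "ImagePyramid",
    "generate_identity_prototypes",
    "render_prototype",
    "render_stimulus_set",
    "build_pyramid",
    "save_stimulus_set",
    "load_stimulus_set",
]

#: canonical feature layout in units of a 64-px face; scaled for other sizes
_CANON = dict(
    head_center=(32.0, 34.0),
    head_axes=(22.0, 27.0),
    eye_y=24.0,
    eye_dx=10.0,
    eye_axes=(4.5, 2.5),
    nose_apex=(32.0, 36.0),
    nose_width=7.0,
    mouth_center=(32.0, 46.0),
    mouth_width=13.0,
    skin=0.72,
    eye_level=0.15,
    nose_level=0.45,
    mouth_level=0.25,
)


@dataclasses.dataclass(frozen=True)
class IdentityPrototype:
    """Geometry and intensity parameters of one synthetic identity."""

    identity_id: int
    eye_centers: tuple  # ((xl, yl), (xr, yr)) in px
    eye_axes: tuple  # ((ax, ay) left, (ax, ay) right)
    nose_apex: tuple  # (x, y)
    nose_width: float
    mouth_center: tuple  # (x, y)
    mouth_width: float
    face_axes: tuple  # head-ellipse radii (ax, ay)
    intensity_params: dict  # gray levels in [0, 1]
    image_size: int = 64

    def parameter_vector(self) -> np.ndarray:
        """Flat vector of the geometric/intensity parameters (for distances)."""
        return np.array(
            [
                *self.eye_centers[0],
                *self.eye_centers[1],
                *self.eye_axes[0],
                *self.eye_axes[1],
                *self.nose_apex,
                self.nose_width,
                *self.mouth_center,
                self.mouth_width,
                *self.face_axes,
                self.intensity_params["skin"],
                self.intensity_params["eye"],
                self.intensity_params["nose"],
                self.intensity_params["mouth"],
            ]
        )

    def validate(self) -> None:
        (xl, yl), (xr, yr) = self.eye_centers
        if not xl < xr:
            raise ValueError("left eye must be left of right eye")
        eye_y = 0.5 * (yl + yr)
        if not eye_y < self.nose_apex[1] < self.mouth_center[1]:
            raise ValueError("feature ordering eye < nose < mouth violated")
        cx, cy = self.image_size / 2.0, self.image_size / 2.0 + self.image_size / 32.0
        ax, ay = self.face_axes
        for x, y in (*self.eye_centers, self.nose_apex, self.mouth_center):
            if not (0 <= x < self.image_size and 0 <= y < self.image_size):
                raise ValueError("feature centre outside image")
            if ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 >= 1.0:
                raise ValueError("feature centre outside head ellipse")


@dataclasses.dataclass
class StimulusSet:
    """Labelled grayscale images with a train/validation split flag."""

    images: list  # of (S, S) float arrays in [0, 1]
    labels: np.ndarray  # (N,) int identity ids
    split: np.ndarray  # (N,) str, "train" or "val"
    image_size: int

    def subset(self, which: str) -> tuple:
        idx = np.flatnonzero(self.split == which)
        return [self.images[i] for i in idx], self.labels[idx]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))


@dataclasses.dataclass(frozen=True)
class ImagePyramid:
    """Three-level average-pool pyramid: full, half and quarter resolution.

    Level 0 is the original image and carries the highest spatial
    frequency (32 cycles/face); levels 1 and 2 carry 16 and 8
    cycles/face respectively.
    """

    levels: tuple  # 3 arrays, sides S, S/2, S/4
    level_meta: tuple = (32, 16, 8)  # cycles/face


def generate_identity_prototypes(n_identities: int, rng_seed: int, image_size: int = 64) -> list:
    """Draw identity prototypes with distinctive eye/nose/mouth geometry.

    Each identity jitters the canonical layout: eye separation and
    height, eye size, nose apex and width, mouth position and width,
    head-ellipse radii, and region gray levels.  Jitter scales with
    ``image_size`` so geometry is resolution-independent.
    """
    if n_identities < 2:
        raise ValueError("need at least 2 identities")
    rng = np.random.default_rng(rng_seed)
    s = image_size / 64.0
    protos = []
    for i in range(n_identities):
        while True:
            eye_y = (_CANON["eye_y"] + rng.uniform(-3.5, 3.5)) * s
            eye_dx = (_CANON["eye_dx"] + rng.uniform(-3.5, 3.5)) * s
            cx = image_size / 2.0
            eye_axes = tuple(
                (
                    _CANON["eye_axes"][0] * rng.uniform(0.7, 1.3) * s,
                    _CANON["eye_axes"][1] * rng.uniform(0.7, 1.3) * s,
                )
                for _ in range(2)
            )
            nose_apex = (
                cx + rng.uniform(-1.5, 1.5) * s,
                (_CANON["nose_apex"][1] + rng.uniform(-3.0, 3.0)) * s,
            )
            mouth_center = (
                cx + rng.uniform(-1.5, 1.5) * s,
                (_CANON["mouth_center"][1] + rng.uniform(-3.5, 3.5)) * s,
            )
            proto = IdentityPrototype(
                identity_id=i,
                eye_centers=((cx - eye_dx, eye_y), (cx + eye_dx, eye_y)),
                eye_axes=eye_axes,
                nose_apex=nose_apex,
                nose_width=(_CANON["nose_width"] + rng.uniform(-2.5, 2.5)) * s,
                mouth_center=mouth_center,
                mouth_width=(_CANON["mouth_width"] + rng.uniform(-4.0, 4.0)) * s,
                face_axes=(
                    _CANON["head_axes"][0] * rng.uniform(0.9, 1.1) * s,
                    _CANON["head_axes"][1] * rng.uniform(0.9, 1.1) * s,
                ),
                intensity_params=dict(
                    skin=float(np.clip(_CANON["skin"] + rng.uniform(-0.08, 0.08), 0, 1)),
                    eye=float(np.clip(_CANON["eye_level"] + rng.uniform(-0.08, 0.08), 0, 1)),
                    nose=float(np.clip(_CANON["nose_level"] + rng.uniform(-0.08, 0.08), 0, 1)),
                    mouth=float(np.clip(_CANON["mouth_level"] + rng.uniform(-0.08, 0.08), 0, 1)),
                ),
                image_size=image_size,
            )
            try:
                proto.validate()
            except ValueError:
                continue  # re-draw this identity
            protos.append(proto)
            break
    return protos


def _ellipse_mask(X, Y, center, axes):
    return ((X - center[0]) / axes[0]) ** 2 + ((Y - center[1]) / axes[1]) ** 2 <= 1.0


def render_prototype(
    proto: IdentityPrototype,
    shift: tuple = (0.0, 0.0),
    intensity_jitter: dict | None = None,
) -> np.ndarray:
    """Rasterise one prototype as an (S, S) float image in [0, 1]."""
    S = proto.image_size
    Y, X = np.mgrid[0:S, 0:S].astype(float)
    X = X - shift[0]
    Y = Y - shift[1]
    iv = dict(proto.intensity_params)
    if intensity_jitter:
        for k, dv in intensity_jitter.items():
            iv[k] = float(np.clip(iv[k] + dv, 0, 1))
    img = np.full((S, S), 0.05)
    head_center = (S / 2.0, S / 2.0 + S / 32.0)
    img[_ellipse_mask(X, Y, head_center, proto.face_axes)] = iv["skin"]
    # nose: a wedge from the eye midline down to the apex
    eye_mid_y = 0.5 * (proto.eye_centers[0][1] + proto.eye_centers[1][1])
    nx, ny = proto.nose_apex
    frac = np.clip((Y - eye_mid_y) / max(ny - eye_mid_y, 1e-9), 0, 1)
    nose = (np.abs(X - nx) <= 0.5 * proto.nose_width * frac) & (Y >= eye_mid_y) & (Y <= ny + 1.5)
    img[nose] = iv["nose"]
    for c, a in zip(proto.eye_centers, proto.eye_axes):
        img[_ellipse_mask(X, Y, c, a)] = iv["eye"]
    mouth_axes = (0.5 * proto.mouth_width, max(1.5 * S / 64.0, 1.0))
    img[_ellipse_mask(X, Y, proto.mouth_center, mouth_axes)] = iv["mouth"]
    return img


def render_stimulus_set(
    prototypes: list,
    exemplars_per_identity: int,
    noise_sd: float = 0.03,
    rng_seed: int = 0,
    jitter_px: float = 1.0,
    intensity_jitter_sd: float = 0.02,
    val_fraction: float = 0.1,
) -> StimulusSet:
    """Render exemplars with position/intensity jitter plus pixel noise.

    Each exemplar translates the whole face by a random sub-pixel shift
    (``jitter_px`` is stated at the 64-px reference scale and scales
    with the image size, like the prototype geometry), jitters the
    region gray levels, adds i.i.d. Gaussian pixel noise of SD
    ``noise_sd``, and clips to [0, 1].  The split is stratified: per
    identity, round(``val_fraction`` * n) exemplars (at least 1, at
    most n - 1) are validation.
    """
    if exemplars_per_identity < 2:
        raise ValueError("need at least 2 exemplars per identity to populate both splits")
    rng = np.random.default_rng(rng_seed)
    size = prototypes[0].image_size
    jitter_px = jitter_px * size / 64.0
    images, labels, split = [], [], []
    for proto in prototypes:
        n = exemplars_per_identity
        n_val = int(np.clip(round(val_fraction * n), 1, n - 1))
        val_idx = set(rng.choice(n, size=n_val, replace=False).tolist())
        for e in range(n):
            shift = rng.uniform(-jitter_px, jitter_px, size=2)
            ij = {k: rng.normal(0, intensity_jitter_sd) for k in ("skin", "eye", "nose", "mouth")}
            img = render_prototype(proto, shift=tuple(shift), intensity_jitter=ij)
            img = np.clip(img + rng.normal(0, noise_sd, img.shape), 0, 1) if noise_sd > 0 else img
            images.append(img)
            labels.append(proto.identity_id)
            split.append("val" if e in val_idx else "train")
    return StimulusSet(
        images=images,
        labels=np.asarray(labels),
        split=np.asarray(split),
        image_size=size,
    )


def build_pyramid(image: np.ndarray) -> ImagePyramid:
    """Three-level pyramid by repeated 2x2 average pooling.

    Average pooling is anti-aliased in the sense required here (it is
    mean-preserving), and pooling a constant image yields the same
    constant at every level.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square and single-channel")
    if image.shape[0] % 4 != 0:
        raise ValueError("image side must be divisible by 4")
    levels = [image]
    for _ in range(2):
        prev = levels[-1]
        h = prev.shape[0] // 2
        levels.append(prev.reshape(h, 2, h, 2).mean(axis=(1, 3)))
    return ImagePyramid(levels=tuple(levels))


# ---------------------------------------------------------------------------
# directory-of-PNGs interchange
# ---------------------------------------------------------------------------

def save_stimulus_set(stimuli: StimulusSet, directory) -> None:
    """Write PNGs named ``id<label>_ex<index>.png`` plus ``manifest.csv``."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict = {}
    for img, label, split in zip(stimuli.images, stimuli.labels, stimuli.split):
        e = counters.get(int(label), 0)
        counters[int(label)] = e + 1
        name = f"id{int(label)}_ex{e}.png"
        Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8), mode="L").save(
            directory / name
        )
        rows.append(dict(filename=name, identity=int(label), split=split))
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def load_stimulus_set(directory) -> StimulusSet:
    """Load any directory of grayscale PNGs described by a manifest CSV."""
    directory = pathlib.Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    for col in ("filename", "identity", "split"):
        if col not in manifest.columns:
            raise ValueError(f"manifest.csv missing required column {col!r}")
    images, labels, split = [], [], []
    for row in manifest.itertuples(index=False):
        img = np.asarray(Image.open(directory / row.filename).convert("L"), dtype=float) / 255.0
        images.append(img)
        labels.append(int(row.identity))
        split.append(str(row.split))
    return StimulusSet(
        images=images,
        labels=np.asarray(labels),
        split=np.asarray(split),
        image_size=images[0].shape[0],
    )
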