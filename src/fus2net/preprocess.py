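"""Image preprocessing: flip-based class balancing, bilinear resize,
channel-mode conversion, per-image zero-mean standardization, and
training-time augmentation.

The pipeline order is: balance -> resize -> (augment, training only) ->
standardize; standardization is always the last step before the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import ImageSample, LabeledDataset


@dataclass
class AugmentConfig:
    """Stochastic, label-preserving transform ranges.

    Magnitudes default to conventional mild settings: rotation up to ±20°,
    shifts up to ±10% of the frame, shear ±0.2, brightness scaling in
    [0.8, 1.2], plus horizontal/vertical flips.  Out-of-frame regions are
    filled with nearest-edge values so speckle images gain no black borders.
    """

    rotation_range: float = 20.0
    shift_range: float = 0.10
    shear_range: float = 0.2
    brightness_range: tuple[float, float] = (0.8, 1.2)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.rotation_range < 0 or self.shift_range < 0 or self.shear_range < 0:
            raise ValueError("augmentation ranges must be non-negative")
        lo, hi = self.brightness_range
        if lo > hi or lo < 0:
            raise ValueError("brightness_range must be a non-negative interval")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(enabled=False)


@dataclass
class PreprocessConfig:
    target_size: int = 299
    channel_mode: str = "three"  # {"one", "three"}
    balance_flip_count: int = 0
    standardize: bool = True
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.balance_flip_count < 0:
            raise ValueError("balance_flip_count must be non-negative")
        if self.channel_mode not in ("one", "three"):
            raise ValueError("channel_mode must be 'one' or 'three'")


def flip_image(sample: ImageSample, direction: str) -> ImageSample:
    """Horizontal or vertical mirror of a sample (new id derived from parent)."""
    if direction == "horizontal":
        px = sample.pixels[:, ::-1, :]
    elif direction == "vertical":
        px = sample.pixels[::-1, :, :]
    else:
        raise ValueError(f"unknown flip direction {direction!r}")
    return ImageSample(
        pixels=px.copy(),
        label=sample.label,
        sample_id=f"{sample.sample_id}-{direction[0]}flip",
    )


def balance_by_flip(
    dataset: LabeledDataset, n_select: int, rng: np.random.Generator
) -> LabeledDataset:
    """Oversample the minority class by flipping randomly chosen images.

    ``n_select`` minority images are drawn without replacement; each
    contributes a horizontal and a vertical mirror, so the minority count
    grows by exactly ``2 * n_select``.  Originals are retained unchanged.
    With the clinical split (646 benign / 306 malignant) and ``n_select=170``
    the malignant count reaches 646 and the classes balance exactly.
    """
    counts = dataset.class_counts
    minority = min(counts, key=counts.get)
    if n_select > counts[minority]:
        raise ValueError(
            f"n_select={n_select} exceeds minority class size {counts[minority]}"
        )
    out = LabeledDataset(list(dataset.samples))
    if n_select == 0:
        return out
    minority_idx = [i for i, s in enumerate(dataset.samples) if s.label == minority]
    chosen = rng.choice(len(minority_idx), size=n_select, replace=False)
    for j in sorted(chosen):
        parent = dataset.samples[minority_idx[j]]
        out.append(flip_image(parent, "horizontal"))
        out.append(flip_image(parent, "vertical"))
    return out


def _resize_plane(plane: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resample with half-pixel-center alignment."""
    in_h, in_w = plane.shape
    ys = (np.arange(out_h) + 0.5) * in_h / out_h - 0.5
    xs = (np.arange(out_w) + 0.5) * in_w / out_w - 0.5
    grid = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(
        plane.astype(np.float64), grid, order=1, mode="nearest"
    )


def resize_bilinear(sample: ImageSample, target_size: int) -> ImageSample:
    """Resize to ``target_size`` x ``target_size`` by bilinear interpolation.

    Output sample centres align with input sample centres under the
    half-pixel convention; values stay within [0, 255] because bilinear
    weights are convex.
    """
    if target_size <= 1:
        raise ValueError("target_size must be > 1")
    planes = [
        _resize_plane(sample.pixels[:, :, c], target_size, target_size)
        for c in range(sample.channels)
    ]
    px = np.clip(np.rint(np.stack(planes, axis=2)), 0, 255).astype(np.uint8)
    return ImageSample(pixels=px, label=sample.label, sample_id=sample.sample_id)


def standardize(pixels: np.ndarray) -> np.ndarray:
    """Per-image zero-mean, unit-variance standardization x* = (x - mu) / sigma.

    mu and sigma (population form) are taken over all pixels and channels of
    the single image.  A constant image (sigma = 0) maps to all zeros.
    """
    x = np.asarray(pixels, dtype=np.float64)
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        return np.zeros_like(x)
    return (x - mu) / sigma


def standardize_sample(sample: ImageSample) -> np.ndarray:
    return standardize(sample.pixels)


def augment(
    sample: ImageSample, cfg: AugmentConfig, rng: np.random.Generator
) -> ImageSample:
    """Randomly rotate/shift/shear/rescale-brightness/flip one image.

    Deterministic given the rng state; with ``enabled=False`` (or all ranges
    null) the input is returned unchanged.  Geometric resampling is bilinear
    with nearest-edge fill; brightness scaling clips to [0, 255].
    """
    if not cfg.enabled:
        return sample
    h, w = sample.height, sample.width
    angle = np.deg2rad(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    ty = rng.uniform(-cfg.shift_range, cfg.shift_range) * h
    tx = rng.uniform(-cfg.shift_range, cfg.shift_range) * w
    shear = rng.uniform(-cfg.shear_range, cfg.shear_range)
    bright = rng.uniform(*cfg.brightness_range)
    do_h = cfg.horizontal_flip and rng.random() < 0.5
    do_v = cfg.vertical_flip and rng.random() < 0.5

    # rotation * shear about the image centre, then translation
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    shr = np.array([[1.0, shear], [0.0, 1.0]])
    mat = rot @ shr
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - mat @ centre + np.array([ty, tx])

    identity_geometry = (
        angle == 0.0 and shear == 0.0 and tx == 0.0 and ty == 0.0
    )
    out = sample.pixels.astype(np.float64)
    if not identity_geometry:
        out = np.stack(
            [
                ndimage.affine_transform(
                    out[:, :, c], mat, offset=offset, order=1, mode="nearest"
                )
                for c in range(sample.channels)
            ],
            axis=2,
        )
    out = np.clip(np.rint(out * bright), 0, 255).astype(np.uint8)
    if do_h:
        out = out[:, ::-1, :]
    if do_v:
        out = out[::-1, :, :]
    return ImageSample(pixels=out, label=sample.label, sample_id=sample.sample_id)


def to_channel_mode(sample: ImageSample, mode: str) -> ImageSample:
    """Convert between one- and three-channel encodings.

    one -> three replicates the gray plane; three -> one averages the
    channels and rounds to the nearest integer.  Idempotent when the sample
    is already in the requested mode.
    """
    if mode not in ("one", "three"):
        raise ValueError(f"mode must be 'one' or 'three', got {mode!r}")
    c = sample.channels
    if mode == "three":
        if c == 3:
            return sample
        px = np.repeat(sample.pixels, 3, axis=2)
    else:
        if c == 1:
            return sample
        px = np.rint(sample.pixels.mean(axis=2, keepdims=True)).astype(np.uint8)
    return ImageSample(pixels=px, label=sample.label, sample_id=sample.sample_id)


def prepare_dataset(dataset: LabeledDataset, cfg: PreprocessConfig) -> LabeledDataset:
    """Balance (optional), resize and channel-convert a dataset.

    Standardization and augmentation are *not* applied here: augmentation is
    drawn per batch at training time and standardization is the final
    per-image step performed when tensors are assembled for the network.
    """
    ds = dataset
    if cfg.balance_flip_count > 0:
        rng = np.random.default_rng(cfg.seed)
        ds = balance_by_flip(ds, cfg.balance_flip_count, rng)
    out = []
    for s in ds:
        s2 = s
        if (s.height, s.width) != (cfg.target_size, cfg.target_size):
            s2 = resize_bilinear(s2, cfg.target_size)
        s2 = to_channel_mode(s2, cfg.channel_mode)
        out.append(s2)
    return LabeledDataset(out)


def as_batch(samples: list[ImageSample], standardize_images: bool = True) -> np.ndarray:
    """Stack samples into a float batch (n, H, W, C), standardized per image."""
    if standardize_images:
        return np.stack([standardize(s.pixels) for s in samples])
    return np.stack([s.pixels.astype(np.float64) for s in samples])
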