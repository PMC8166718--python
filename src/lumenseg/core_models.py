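"""The two single-frame core segmentation models.

``m1`` is a U-Net whose convolutional blocks are residual units (two 3x3
convolutions with an identity shortcut, 1x1 projection when channel counts
differ), ending in a 1x1 convolution + sigmoid that emits one lumen
probability channel.

``m2`` is a compact detect-and-segment instance core: a plain (non-residual)
encoder-decoder FCN proposes a per-pixel foreground probability field, from
which candidate instances are extracted as connected components, scored by
their mean interior probability, filtered by a detection-confidence
threshold and anchor-scale size priors, and merged into a single lumen
probability map by :func:`instances_to_lumen_map`.

Both models consume frames resized to a fixed square working resolution
(videos differ in native size); predictions are resized back to native
dimensions before any metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .errors import ConfigError, InputError, ShapeError
from .image_io import Frame

DEFAULT_WORKING_SIZE = 256


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel lumen probability for one frame."""

    pixels: np.ndarray  # (p, q) float in [0, 1]
    t: int = 0
    model_tag: str = ""

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=np.float32)
        if arr.ndim != 2:
            raise InputError("probability map must be 2-D")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise InputError("probability values must lie in [0, 1]")
        object.__setattr__(self, "pixels", arr)


@dataclass(frozen=True)
class ResUNetSpec:
    """Architecture description for the residual U-Net core (m1)."""

    depth: int = 4
    base_filters: int = 32
    input_shape: Tuple[int, int, int] = (DEFAULT_WORKING_SIZE,
                                         DEFAULT_WORKING_SIZE, 3)
    use_batch_norm: bool = True

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigError("depth must be at least 2")
        if self.base_filters < 8:
            raise ConfigError("base_filters must be at least 8")
        p, q = self.input_shape[0], self.input_shape[1]
        if p % (1 << self.depth) or q % (1 << self.depth):
            raise ConfigError(
                f"input dims {p}x{q} must be divisible by 2^depth = {1 << self.depth}")


@dataclass(frozen=True)
class InstanceSegSpec:
    """Configuration for the instance-segmentation core (m2)."""

    backbone: Literal["resnet50", "resnet101"] = "resnet50"
    min_detection_confidence: float = 0.7
    anchor_scales: Tuple[int, ...] = (32, 64, 128, 160)
    input_channels: int = 3
    input_size: int = DEFAULT_WORKING_SIZE

    def __post_init__(self):
        if self.backbone not in ("resnet50", "resnet101"):
            raise ConfigError("backbone must be resnet50 or resnet101")
        if not (0.5 <= self.min_detection_confidence <= 0.9):
            raise ConfigError("min_detection_confidence must lie in [0.5, 0.9]")
        scales = tuple(self.anchor_scales)
        if any(s <= 0 for s in scales) or any(
                b <= a for a, b in zip(scales, scales[1:])):
            raise ConfigError("anchor_scales must be strictly increasing, positive")


class _ResidualBlock(nn.Module):
    def __init__(self, cin, cout, rng, use_bn=True):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, pad=1)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, pad=1)
        self.bn1 = nn.BatchNorm2d(cout) if use_bn else None
        self.bn2 = nn.BatchNorm2d(cout) if use_bn else None
        self.proj = nn.Conv2d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x):
        h = self.conv1(x)
        if self.bn1 is not None:
            h = self.bn1(h)
        h = nn.relu(h)
        h = self.conv2(h)
        if self.bn2 is not None:
            h = self.bn2(h)
        s = self.proj(x) if self.proj is not None else x
        return nn.relu(nn.add(h, s))


class _DoubleConvBlock(nn.Module):
    """Plain (non-residual) double 3x3 conv block for the instance core."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, pad=1)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, pad=1)
        self.bn1 = nn.BatchNorm2d(cout)
        self.bn2 = nn.BatchNorm2d(cout)

    def __call__(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(h)))


class SegmentationModel(nn.Module):
    """Common surface: forward() on NCHW tensors, predict_proba() on frames."""

    temporal = False
    model_tag = ""
    input_channels = 3
    fixed_input_channels = False
    input_size: int | None = None

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        raise NotImplementedError

    def predict_proba(self, frames: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Run inference on an (N, H, W, C) stack; returns (N, H, W) in [0,1]."""
        frames = np.asarray(frames, dtype=np.float32)
        if frames.ndim != 4 or frames.shape[3] != self.input_channels:
            raise ShapeError(
                f"expected (N,H,W,{self.input_channels}), got {frames.shape}")
        self.eval()
        outs = []
        for i in range(0, len(frames), batch_size):
            probs = self.forward(nn.Tensor(frames[i:i + batch_size]))
            outs.append(probs.data[..., 0])
        return np.concatenate(outs, axis=0)


class ResUNet(SegmentationModel):
    """Residual-block U-Net emitting a single sigmoid probability channel."""

    model_tag = "m1"

    def __init__(self, spec: ResUNetSpec, rng: np.random.Generator,
                 input_channels: int = 3):
        super().__init__()
        self.spec = spec
        self.input_channels = input_channels
        self.input_size = spec.input_shape[0]
        f = [spec.base_filters << d for d in range(spec.depth + 1)]
        bn = spec.use_batch_norm
        self.enc = [_ResidualBlock(input_channels if d == 0 else f[d - 1],
                                   f[d], rng, bn) for d in range(spec.depth)]
        self.bottleneck = _ResidualBlock(f[spec.depth - 1], f[spec.depth], rng, bn)
        self.ups = [nn.ConvTranspose2d(f[d + 1], f[d], rng)
                    for d in reversed(range(spec.depth))]
        self.dec = [_ResidualBlock(2 * f[d], f[d], rng, bn)
                    for d in reversed(range(spec.depth))]
        self.head = nn.Conv2d(f[0], 1, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h, w = x.shape[1], x.shape[2]
        if h % (1 << self.spec.depth) or w % (1 << self.spec.depth):
            raise ShapeError(f"input {h}x{w} not divisible by 2^depth")
        skips = []
        h_t = x
        for block in self.enc:
            h_t = block(h_t)
            skips.append(h_t)
            h_t = nn.maxpool2d_2x2(h_t)
        h_t = self.bottleneck(h_t)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            h_t = up(h_t)
            h_t = block(nn.concat_channels(skip, h_t))
        return nn.sigmoid(self.head(h_t))


def build_resunet(spec: ResUNetSpec, seed: int = 0,
                  input_channels: int = 3) -> ResUNet:
    """Construct m1 from its spec with seeded He-normal initialization."""
    return ResUNet(spec, np.random.default_rng(seed), input_channels)


class InstanceSegCore(SegmentationModel):
    """Compact detect-and-segment core (m2).

    The encoder width follows the backbone choice (the deeper backbone maps
    to a wider feature extractor).  The stem channel count is fixed at
    construction, mirroring a pretrained backbone's frozen input contract:
    temporal extensions must match it exactly.
    """

    model_tag = "m2"
    fixed_input_channels = True

    def __init__(self, spec: InstanceSegSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.input_channels = spec.input_channels
        self.input_size = spec.input_size
        base = 16 if spec.backbone == "resnet101" else 12
        self.enc1 = _DoubleConvBlock(spec.input_channels, base, rng)
        self.enc2 = _DoubleConvBlock(base, 2 * base, rng)
        self.bottleneck = _DoubleConvBlock(2 * base, 4 * base, rng)
        self.up2 = nn.ConvTranspose2d(4 * base, 2 * base, rng)
        self.dec2 = _DoubleConvBlock(4 * base, 2 * base, rng)
        self.up1 = nn.ConvTranspose2d(2 * base, base, rng)
        self.dec1 = _DoubleConvBlock(2 * base, base, rng)
        self.head = nn.Conv2d(base, 1, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] % 4 or x.shape[2] % 4:
            raise ShapeError("input dims must be divisible by 4")
        e1 = self.enc1(x)
        e2 = self.enc2(nn.maxpool2d_2x2(e1))
        b = self.bottleneck(nn.maxpool2d_2x2(e2))
        d2 = self.dec2(nn.concat_channels(e2, self.up2(b)))
        d1 = self.dec1(nn.concat_channels(e1, self.up1(d2)))
        return nn.sigmoid(self.head(d1))

    def extract_instances(self, prob_map: np.ndarray,
                          proposal_threshold: float = 0.5):
        """Connected-component instance proposals with soft masks and scores.

        Components larger than twice the largest anchor scale in extent or
        smaller than 4 px are discarded (size priors); the score is the mean
        probability inside the component.
        """
        labels, n = ndimage.label(prob_map >= proposal_threshold)
        masks, scores = [], []
        max_extent = 2 * max(self.spec.anchor_scales)
        for lab in range(1, n + 1):
            comp = labels == lab
            area = int(comp.sum())
            if area < 4:
                continue
            rows = np.any(comp, axis=1)
            cols = np.any(comp, axis=0)
            extent = max(int(rows.sum()), int(cols.sum()))
            if extent > max_extent:
                continue
            soft = np.where(comp, prob_map, 0.0).astype(np.float32)
            masks.append(soft)
            scores.append(float(prob_map[comp].mean()))
        return masks, scores

    def predict_proba(self, frames: np.ndarray, batch_size: int = 16) -> np.ndarray:
        raw = super().predict_proba(frames, batch_size)
        out = np.empty_like(raw)
        for i, pm in enumerate(raw):
            masks, scores = self.extract_instances(pm)
            out[i] = instances_to_lumen_map(
                masks, scores, self.spec.min_detection_confidence,
                shape=pm.shape).pixels
        return out


def build_instance_core(spec: InstanceSegSpec, seed: int = 0) -> InstanceSegCore:
    return InstanceSegCore(spec, np.random.default_rng(seed))


def instances_to_lumen_map(instance_masks: Sequence[np.ndarray],
                           scores: Sequence[float],
                           confidence_threshold: float,
                           merge_policy: Literal["best", "union"] = "best",
                           t: int = 0, model_tag: str = "m2",
                           shape: Tuple[int, int] | None = None
                           ) -> ProbabilityMap:
    """Merge scored soft instance masks into one lumen probability map.

    Instances scoring below ``confidence_threshold`` are discarded.  With
    ``best`` the highest-scoring survivor's soft mask is returned unchanged
    (the lumen is a single region in this anatomy); ``union`` takes the
    pixelwise maximum over survivors.  No survivors yields an all-zero map.
    """
    if len(instance_masks) != len(scores):
        raise InputError("instance_masks and scores must have equal length")
    if any(not (0.0 <= s <= 1.0) for s in scores):
        raise InputError("scores must lie in [0, 1]")
    if merge_policy not in ("best", "union"):
        raise ConfigError(f"unknown merge policy {merge_policy!r}")
    survivors = [(m, s) for m, s in zip(instance_masks, scores)
                 if s >= confidence_threshold]
    if shape is None:
        if instance_masks:
            shape = np.asarray(instance_masks[0]).shape
        else:
            raise InputError("shape required when no instances are supplied")
    if not survivors:
        return ProbabilityMap(np.zeros(shape, dtype=np.float32), t, model_tag)
    if merge_policy == "best":
        best = max(survivors, key=lambda ms: ms[1])
        return ProbabilityMap(np.asarray(best[0], dtype=np.float32), t, model_tag)
    fused = np.max(np.stack([np.asarray(m, dtype=np.float32)
                             for m, _ in survivors]), axis=0)
    return ProbabilityMap(fused, t, model_tag)


def resize_frame(pixels: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an (H, W, C) frame to (size, size, C)."""
    if pixels.shape[0] == size and pixels.shape[1] == size:
        return pixels.astype(np.float32)
    out = resize(pixels, (size, size), order=1, anti_aliasing=False,
                 preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def resize_map(pixels: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a probability map back to native frame dims."""
    if pixels.shape == tuple(shape):
        return pixels.astype(np.float32)
    out = resize(pixels, shape, order=1, anti_aliasing=False,
                 preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def predict_single(model: SegmentationModel, frame: Frame) -> ProbabilityMap:
    """Segment one still frame with a single-frame core model."""
    if model.temporal:
        raise ShapeError("temporal models require a FrameTriplet; "
                         "use predict_triplet")
    pixels = frame.pixels
    native = pixels.shape[:2]
    if model.input_size is not None:
        pixels = resize_frame(pixels, model.input_size)
    pm = model.predict_proba(pixels[None])[0]
    return ProbabilityMap(resize_map(pm, native), t=frame.t,
                          model_tag=model.model_tag)
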