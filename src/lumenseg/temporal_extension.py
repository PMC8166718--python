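"""Multi-frame extension of a single-frame core model.

A core model m becomes a spatio-temporal model M by prepending one 3D
convolution over a triplet of consecutive frames.  With r = 3 input frames
and kernels of size (r x 3 x 3), the valid convolution consumes the whole
temporal extent and emits a feature block of shape (1, p-2, q-2, n_k); the
lost spatial ring is restored by symmetric zero padding and the leading
singleton axis is squeezed, so the (p, q, n_k) block feeds straight into the
core.  The core's prediction then refers to the central frame I(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Tuple, Union

import numpy as np

from . import nn
from .core_models import (InstanceSegCore, InstanceSegSpec, ProbabilityMap,
                          ResUNet, ResUNetSpec, SegmentationModel,
                          build_instance_core, instances_to_lumen_map,
                          resize_frame, resize_map)
from .errors import ConfigError, InputError, ShapeError
from .image_io import FrameTriplet

R_TEMPORAL = 3  # temporal extent: exactly three consecutive frames


@dataclass(frozen=True)
class TemporalExtensionSpec:
    """Configuration of the prepended 3D convolution."""

    n_k: int = 8
    r: int = R_TEMPORAL
    kernel_spatial: Tuple[int, int] = (3, 3)
    activation: Literal["linear", "relu"] = "relu"

    def __post_init__(self):
        if self.r != R_TEMPORAL:
            raise ConfigError(f"temporal extent is fixed at r = {R_TEMPORAL}")
        if self.n_k < 1:
            raise ConfigError("n_k must be at least 1")
        if tuple(self.kernel_spatial) != (3, 3):
            raise ConfigError("kernel shape is fixed at (r x 3 x 3)")
        if self.activation not in ("linear", "relu"):
            raise ConfigError("activation must be 'linear' or 'relu'")


class TemporalFrontResult(NamedTuple):
    raw: np.ndarray       # (1, p-2, q-2, n_k) valid-convolution output
    features: np.ndarray  # (p, q, n_k) zero-padded, activation applied


def temporal_front(triplet: FrameTriplet, spec: TemporalExtensionSpec,
                   weights: np.ndarray, bias: np.ndarray | None = None
                   ) -> TemporalFrontResult:
    """Apply the 3D front convolution to one frame triplet.

    ``weights`` has shape (n_k, r, 3, 3, n_c).  The raw valid output keeps
    its singleton temporal axis, shape (1, p-2, q-2, n_k); the returned
    feature block is zero-padded by one pixel per spatial border back to
    (p, q, n_k), so its border ring is exactly zero.
    """
    frames = np.stack([f.pixels for f in triplet.frames])  # (r, p, q, n_c)
    r, p, q, n_c = frames.shape
    if p < 3 or q < 3:
        raise ShapeError("frames must be at least 3 x 3 for a 3x3 kernel")
    w = np.asarray(weights, dtype=np.float32)
    if w.shape != (spec.n_k, spec.r, 3, 3, n_c):
        raise ShapeError(f"weights must be (n_k, r, 3, 3, n_c) = "
                         f"({spec.n_k}, {spec.r}, 3, 3, {n_c}), got {w.shape}")
    win = np.lib.stride_tricks.sliding_window_view(frames, (3, 3), axis=(1, 2))
    # win: (r, p-2, q-2, n_c, 3, 3)
    out = np.einsum("tijcab,ktabc->ijk", win, w, optimize=True)
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float32)
    raw = out[None].astype(np.float32)           # (1, p-2, q-2, n_k)
    feat = raw[0]
    if spec.activation == "relu":
        feat = np.maximum(feat, 0.0)
    features = np.pad(feat, ((1, 1), (1, 1), (0, 0)))
    return TemporalFrontResult(raw=raw, features=features.astype(np.float32))


class ExtendedModel(SegmentationModel):
    """Core model with the 3D-convolution front; consumes frame triplets
    stacked channelwise as (N, H, W, r*n_c)."""

    temporal = True

    def __init__(self, core: SegmentationModel, spec: TemporalExtensionSpec,
                 rng: np.random.Generator, n_c: int = 3):
        super().__init__()
        if core.temporal:
            raise ConfigError("core model is already temporal")
        if core.fixed_input_channels and spec.n_k != core.input_channels:
            raise ConfigError(
                f"n_k = {spec.n_k} incompatible with the fixed {core.input_channels}"
                f"-channel input of the {type(core).__name__} core")
        self.tspec = spec
        self.n_c = n_c
        self.core = core
        # (n_k, r*n_c, 3, 3) == n_k kernels of size (r x 3 x 3) over n_c channels
        self.front = nn.Conv2d(spec.r * n_c, spec.n_k, 3, rng, pad=0)
        self.model_tag = "M" + core.model_tag[1:] if core.model_tag else "M"
        self.input_channels = spec.r * n_c
        self.input_size = core.input_size

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] < 3 or x.shape[2] < 3:
            raise ShapeError("spatial dims must be at least 3")
        h = self.front(x)                 # valid conv: (N, H-2, W-2, n_k)
        if self.tspec.activation == "relu":
            h = nn.relu(h)
        h = nn.pad2d(h, 1)                # zero ring restores (N, H, W, n_k)
        return self.core.forward(h)

    def front_parameter_count(self) -> int:
        return self.front.weight.data.size + self.front.bias.data.size

    def predict_proba(self, frames: np.ndarray, batch_size: int = 16) -> np.ndarray:
        if isinstance(self.core, InstanceSegCore):
            raw = SegmentationModel.predict_proba(self, frames, batch_size)
            out = np.empty_like(raw)
            for i, pm in enumerate(raw):
                masks, scores = self.core.extract_instances(pm)
                out[i] = instances_to_lumen_map(
                    masks, scores, self.core.spec.min_detection_confidence,
                    shape=pm.shape).pixels
            return out
        return SegmentationModel.predict_proba(self, frames, batch_size)


CoreSpec = Union[ResUNetSpec, InstanceSegSpec]


def extend_model(core_spec: CoreSpec | SegmentationModel,
                 spec: TemporalExtensionSpec, seed: int = 0) -> ExtendedModel:
    """Build an extended model M from a core spec (or an existing core).

    For the residual U-Net core the stem is rebuilt to accept n_k feature
    channels; the instance core's stem is fixed at its pretrained-style
    3-channel contract, so only n_k = 3 is accepted there.
    """
    rng = np.random.default_rng(seed)
    if isinstance(core_spec, ResUNetSpec):
        core = ResUNet(core_spec, rng, input_channels=spec.n_k)
    elif isinstance(core_spec, InstanceSegSpec):
        core = build_instance_core(core_spec, seed=seed + 1)
    elif isinstance(core_spec, SegmentationModel):
        core = core_spec
    else:
        raise ConfigError(f"cannot extend {type(core_spec).__name__}")
    if not isinstance(core_spec, ResUNetSpec) and core.input_channels != spec.n_k:
        raise ConfigError(
            f"n_k = {spec.n_k} does not match the core's "
            f"{core.input_channels}-channel input")
    return ExtendedModel(core, spec, rng)


def triplet_to_input(triplet: FrameTriplet) -> np.ndarray:
    """Stack a triplet channelwise to the (H, W, r*n_c) model input layout."""
    return np.concatenate([f.pixels for f in triplet.frames], axis=2)


def predict_triplet(model: ExtendedModel, triplet: FrameTriplet) -> ProbabilityMap:
    """Segment the central frame of a triplet with an extended model."""
    if not model.temporal:
        raise ShapeError("predict_triplet requires an extended (temporal) model")
    x = triplet_to_input(triplet)
    native = x.shape[:2]
    if model.input_size is not None:
        x = resize_frame(x, model.input_size)
    pm = model.predict_proba(x[None])[0]
    return ProbabilityMap(resize_map(pm, native), t=triplet.center_index,
                          model_tag=model.model_tag)
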