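"""Prediction averaging across member models.

The ensemble function is the arithmetic mean of the k member probability
maps, F(p_i(t)) = (1/k) * sum_i p_i(t), computed on soft probabilities
(members are never thresholded before fusion).  The fused map is binarized
at a configurable threshold (default 0.5, the natural decision boundary for
a mean of probabilities) to produce the final lumen mask.  Any subset of
{m1, m2, M1, M2} can form an ensemble, so single models, the four two-member
ablation variants, and the full four-member ensemble all share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .core_models import ProbabilityMap
from .errors import AlignmentError, ConfigError, InputError
from .image_io import BinaryMask

VALID_MEMBERS = ("m1", "m2", "M1", "M2")


@dataclass(frozen=True)
class EnsembleConfig:
    """Which members to fuse and how to binarize the fused map."""

    members: Tuple[str, ...] = VALID_MEMBERS
    binarize_threshold: float = 0.5

    def __post_init__(self):
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if not (1 <= len(members) <= 4):
            raise ConfigError("ensemble needs between 1 and 4 members")
        if len(set(members)) != len(members):
            raise ConfigError("ensemble members must be unique")
        unknown = set(members) - set(VALID_MEMBERS)
        if unknown:
            raise ConfigError(f"unknown member tags: {sorted(unknown)}")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ConfigError("binarize_threshold must lie in (0, 1)")

    @property
    def k(self) -> int:
        return len(self.members)


def ensemble_predict(maps: Sequence[ProbabilityMap],
                     model_tag: str = "ensemble") -> ProbabilityMap:
    """Fuse member probability maps by their per-pixel arithmetic mean."""
    if not maps:
        raise InputError("ensemble requires at least one probability map")
    shapes = {m.pixels.shape for m in maps}
    if len(shapes) != 1:
        raise AlignmentError(f"member map shapes differ: {sorted(shapes)}")
    ts = {m.t for m in maps}
    if len(ts) != 1:
        raise AlignmentError(f"member maps refer to different frames: {sorted(ts)}")
    stacked = np.stack([m.pixels.astype(np.float64) for m in maps])
    fused = stacked.mean(axis=0).astype(np.float32)
    return ProbabilityMap(np.clip(fused, 0.0, 1.0), t=maps[0].t,
                          model_tag=model_tag)


def binarize(prob_map: ProbabilityMap, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map; a pixel is lumen iff value >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ConfigError("threshold must lie in (0, 1)")
    return BinaryMask((prob_map.pixels >= threshold).astype(np.uint8),
                      t=prob_map.t)


def ensemble_predict_arrays(member_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Array-level fusion for batch pipelines: mean over members of
    (N, H, W) probability stacks."""
    if not member_maps:
        raise InputError("ensemble requires at least one member stack")
    shapes = {m.shape for m in member_maps}
    if len(shapes) != 1:
        raise AlignmentError("member stacks must share shape")
    return np.mean(np.stack([np.asarray(m, dtype=np.float64)
                             for m in member_maps]), axis=0).astype(np.float32)


def table2_variants() -> Tuple[EnsembleConfig, ...]:
    """The four two-member ablation ensembles: spatial only, temporal only,
    and each core paired with its own extension."""
    return (EnsembleConfig(("m1", "m2")), EnsembleConfig(("M1", "M2")),
            EnsembleConfig(("M1", "m1")), EnsembleConfig(("M2", "m2")))
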