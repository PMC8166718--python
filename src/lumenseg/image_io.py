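"""Frame and mask I/O plus triplet assembly.

Endoscopic video arrives either as directories of numbered PNG/JPEG frames
or as common video containers.  Frames are normalized to ``[0, 1]`` floats at
read time (division by the dtype maximum, so 8-bit 255 maps to exactly 1.0).
Within one video every frame must share spatial dimensions; different videos
may differ and are unified later by the training pipeline's resizing step.

Ground-truth masks are single-channel PNGs with foreground 255, stored next
to their frame as ``<frame_stem>_mask.png``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import List, Sequence, Tuple

import imageio.v3 as iio
import numpy as np

from .errors import AlignmentError, EmptySequenceError, FormatError, InputError

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
_VIDEO_EXTS = {".mp4", ".avi", ".mov", ".mkv"}


class BoundaryPolicy(str, Enum):
    """How to form triplets at the first/last frame of a video."""

    REPLICATE_EDGE = "replicate_edge"
    DROP_EDGES = "drop_edges"


class BoundaryFlag(str, Enum):
    INTERIOR = "interior"
    REPLICATED_LEFT = "replicated_left"
    REPLICATED_RIGHT = "replicated_right"


@dataclass
class Frame:
    """One RGB video frame with pixels in [0, 1] and provenance labels."""

    pixels: np.ndarray  # (p, q, 3) float32 in [0, 1]
    t: int
    video_id: str = ""
    patient_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputError(f"frame must be p x q x 3, got {self.pixels.shape}")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise InputError("frame spatial dims must be at least 8 x 8")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise InputError("frame pixel values must lie in [0, 1]")
        if self.t < 0:
            raise InputError("frame index must be non-negative")

    @property
    def spatial_shape(self) -> Tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class FrameTriplet:
    """Three consecutive frames (I(t-1), I(t), I(t+1)) of one video."""

    frames: Tuple[Frame, Frame, Frame]
    center_index: int
    boundary_flag: BoundaryFlag = BoundaryFlag.INTERIOR

    def __post_init__(self):
        if len(self.frames) != 3:
            raise InputError("a triplet needs exactly 3 frames")
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) != 1:
            raise AlignmentError("triplet frames must share p, q, n_c")
        vids = {f.video_id for f in self.frames}
        if len(vids) != 1:
            raise InputError("triplet frames must come from one video")
        if self.frames[1].t != self.center_index:
            raise InputError("center_index must equal the middle frame's t")

    @property
    def center(self) -> Frame:
        return self.frames[1]


@dataclass
class BinaryMask:
    """Per-pixel {0,1} lumen annotation for one frame."""

    pixels: np.ndarray  # (p, q) of {0, 1}
    t: int = 0
    video_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise InputError(f"mask must be 2-D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise InputError("mask values must be exactly 0 or 1")
        self.pixels = arr.astype(np.uint8)


def normalize_pixels(arr: np.ndarray) -> np.ndarray:
    """Scale an integer image by its dtype maximum; floats pass through."""
    if np.issubdtype(arr.dtype, np.integer):
        maxval = np.iinfo(arr.dtype).max
        return (arr.astype(np.float32) / maxval).astype(np.float32)
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


_NUM_RE = re.compile(r"(\d+)")


def _frame_sort_key(path: Path):
    # lexicographic on zero-padded numeric stems: pad every digit run
    return _NUM_RE.sub(lambda m: m.group(1).zfill(12), path.stem), path.stem


def read_frame_sequence(path, video_id: str = "", patient_id: str = "") -> List[Frame]:
    """Read an ordered frame sequence from a directory or a video file.

    Directory frames are ordered by their (zero-padded) numeric filename
    stems; files named ``*_mask*`` are skipped.  All frames of one sequence
    must share spatial dimensions.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such path: {path}")
    arrays: List[np.ndarray] = []
    if path.is_dir():
        files = sorted((f for f in path.iterdir()
                        if f.suffix.lower() in _IMAGE_EXTS
                        and "_mask" not in f.stem),
                       key=_frame_sort_key)
        for f in files:
            try:
                arrays.append(np.asarray(iio.imread(f)))
            except Exception:
                continue
    elif path.suffix.lower() in _VIDEO_EXTS:
        try:
            for frame in iio.imiter(path):
                arrays.append(np.asarray(frame))
        except Exception as exc:
            raise FormatError(f"cannot decode video {path}: {exc}") from exc
    else:
        arrays.append(np.asarray(iio.imread(path)))
    if not arrays:
        raise EmptySequenceError(f"no decodable frames under {path}")
    shapes = {a.shape[:2] for a in arrays}
    if len(shapes) != 1:
        raise FormatError(
            f"inconsistent spatial sizes within one sequence: {sorted(shapes)}")
    vid = video_id or path.stem
    return [Frame(normalize_pixels(_to_rgb(a)), t=i, video_id=vid,
                  patient_id=patient_id) for i, a in enumerate(arrays)]


def make_triplets(frames: Sequence[Frame],
                  boundary_policy: BoundaryPolicy = BoundaryPolicy.REPLICATE_EDGE
                  ) -> List[FrameTriplet]:
    """Assemble (I(t-1), I(t), I(t+1)) triplets from an ordered sequence.

    ``replicate_edge`` duplicates the first/last frame so every frame is a
    triplet center (output length equals input length); ``drop_edges`` keeps
    interior centers only (length ``max(0, n - 2)``).
    """
    frames = list(frames)
    if not frames:
        raise EmptySequenceError("cannot form triplets from an empty sequence")
    policy = BoundaryPolicy(boundary_policy)
    n = len(frames)
    triplets = []
    if policy is BoundaryPolicy.REPLICATE_EDGE:
        for i in range(n):
            left = frames[max(i - 1, 0)]
            right = frames[min(i + 1, n - 1)]
            if i == 0:
                flag = BoundaryFlag.REPLICATED_LEFT
            elif i == n - 1:
                flag = BoundaryFlag.REPLICATED_RIGHT
            else:
                flag = BoundaryFlag.INTERIOR
            triplets.append(FrameTriplet((left, frames[i], right),
                                         center_index=frames[i].t,
                                         boundary_flag=flag))
    else:
        for i in range(1, n - 1):
            triplets.append(FrameTriplet((frames[i - 1], frames[i], frames[i + 1]),
                                         center_index=frames[i].t,
                                         boundary_flag=BoundaryFlag.INTERIOR))
    return triplets


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as a lossless 0/255 single-channel PNG."""
    if not isinstance(mask, BinaryMask):
        mask = BinaryMask(np.asarray(mask))
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))
    except OSError as exc:
        raise InputError(f"cannot write mask to {path}: {exc}") from exc


def read_mask(path, t: int = 0, video_id: str = "") -> BinaryMask:
    """Read a 0/255 PNG mask back into a {0,1} BinaryMask."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such mask file: {path}")
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask((arr > 127).astype(np.uint8), t=t, video_id=video_id)


def mask_path_for(frame_path) -> Path:
    """Conventional mask filename next to a frame: ``<stem>_mask.png``."""
    frame_path = Path(frame_path)
    return frame_path.with_name(frame_path.stem + "_mask.png")
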