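"""Offline dataset augmentation applied jointly to images and masks.

The augmentation set is small and geometric: rotations in steps of 90°,
horizontal and vertical flips, and zooming in or out by at most 2% of the
original size.  One sampled parameter set is applied identically to the
image (or every frame of a triplet) and to its mask, so the pair stays
pixel-aligned; masks are resampled nearest-neighbor to stay binary.
Augmentation runs before training, and augmented copies inherit the source
frame's patient label so patient-wise splits remain leak-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rescale

from .errors import AlignmentError, ConfigError

ZOOM_RANGE = (0.98, 1.02)


@dataclass(frozen=True)
class AugmentationParams:
    """One jointly-applied geometric transform."""

    rotation_quarter_turns: int
    hflip: bool
    vflip: bool
    zoom_factor: float
    seed: int

    def __post_init__(self):
        if self.rotation_quarter_turns not in (0, 1, 2, 3):
            raise ConfigError("rotation must be 0..3 quarter turns")
        if not (ZOOM_RANGE[0] <= self.zoom_factor <= ZOOM_RANGE[1]):
            raise ConfigError(f"zoom factor must lie in {ZOOM_RANGE}")


def sample_augmentation(seed: int) -> AugmentationParams:
    """Draw one parameter set: rotation uniform over the four quarter turns,
    fair coin flips, zoom uniform on [0.98, 1.02].  Deterministic in seed."""
    rng = np.random.default_rng(seed)
    return AugmentationParams(
        rotation_quarter_turns=int(rng.integers(0, 4)),
        hflip=bool(rng.integers(0, 2)),
        vflip=bool(rng.integers(0, 2)),
        zoom_factor=float(rng.uniform(*ZOOM_RANGE)),
        seed=seed,
    )


def _zoom_keep_shape(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom about the center, then center-crop (in) or zero-pad (out) back
    to the original shape.  factor == 1.0 is the exact identity."""
    if factor == 1.0:
        return arr
    h, w = arr.shape[:2]
    channel_axis = -1 if arr.ndim == 3 else None
    scaled = rescale(arr.astype(np.float32), factor, order=order,
                     channel_axis=channel_axis, anti_aliasing=False,
                     preserve_range=True)
    sh, sw = scaled.shape[:2]
    if sh >= h:  # zoom in: crop center
        top, left = (sh - h) // 2, (sw - w) // 2
        out = scaled[top:top + h, left:left + w]
    else:  # zoom out: pad with zeros
        out = np.zeros(arr.shape, dtype=np.float32)
        top, left = (h - sh) // 2, (w - sw) // 2
        out[top:top + sh, left:left + sw] = scaled
    return out.astype(arr.dtype) if arr.dtype == np.uint8 else out


def _apply_geometry(arr: np.ndarray, params: AugmentationParams,
                    order: int) -> np.ndarray:
    out = _zoom_keep_shape(arr, params.zoom_factor, order)
    if params.rotation_quarter_turns:
        out = np.rot90(out, k=params.rotation_quarter_turns, axes=(0, 1))
    if params.hflip:
        out = np.flip(out, axis=1)
    if params.vflip:
        out = np.flip(out, axis=0)
    return np.ascontiguousarray(out)


def apply_augmentation(image, mask, params: AugmentationParams):
    """Apply one transform jointly to an image (array, Frame, or a sequence
    of frames forming a triplet) and its mask.

    Images are resampled bilinearly, masks nearest-neighbor.  Output spatial
    dimensions always equal the input's.  Returns ``(image(s), mask)`` as
    plain arrays (single image) or a list of arrays (triplet input).
    """
    from .image_io import BinaryMask, Frame  # local: avoid import cycle

    mask_arr = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)

    def image_array(img):
        return img.pixels if isinstance(img, Frame) else np.asarray(img)

    if isinstance(image, (list, tuple)):
        imgs = [image_array(i) for i in image]
    else:
        imgs = [image_array(image)]
    for arr in imgs:
        if arr.shape[:2] != mask_arr.shape[:2]:
            raise AlignmentError(
                f"image {arr.shape[:2]} and mask {mask_arr.shape[:2]} differ")
    out_imgs = [np.clip(_apply_geometry(a, params, order=1), 0.0, 1.0)
                for a in imgs]
    out_mask = _apply_geometry(mask_arr.astype(np.uint8), params, order=0)
    out_mask = (out_mask > 0).astype(np.uint8)
    if isinstance(image, (list, tuple)):
        return out_imgs, out_mask
    return out_imgs[0], out_mask


def augment_dataset(ds, copies_per_frame: int = 4, seed: int = 0):
    """Offline expansion of a dataset: ``copies_per_frame`` augmented copies
    of every video, appended to the originals.

    One parameter set is sampled per (video, copy) and applied to every
    frame of that video, so triplets formed inside an augmented copy stay
    temporally coherent.  Copies keep their source frames' patient label
    (patient-wise splits stay leak-free) and get a suffixed video id.
    """
    from .dataset import FrameDataset  # local: avoid import cycle

    if copies_per_frame < 0:
        raise ConfigError("copies_per_frame must be non-negative")
    rng = np.random.default_rng(seed)
    parts = [ds]
    for vid in sorted(set(ds.video_ids.tolist())):
        idx = np.where(ds.video_ids == vid)[0]
        for k in range(copies_per_frame):
            params = sample_augmentation(int(rng.integers(0, 2 ** 31)))
            frames, masks = [], []
            for i in idx:
                img, msk = apply_augmentation(ds.frames[i], ds.masks[i], params)
                frames.append(img)
                masks.append(msk)
            parts.append(FrameDataset(
                np.stack(frames), np.stack(masks),
                ds.patient_ids[idx].copy(),
                np.array([f"{vid}#aug{k}"] * len(idx), dtype=object),
                ds.t[idx].copy(), ds.corrupted[idx].copy()))
    out = parts[0]
    for part in parts[1:]:
        out = out.concat(part)
    return out
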