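"""In-memory dataset container shared by training, evaluation and the CLI.

A :class:`FrameDataset` is a flat stack of frames with per-frame masks and
provenance (patient, video, temporal index), the unit every pipeline stage
operates on.  It can be written to / read from the PNG + ``manifest.csv``
layout that :mod:`lumenseg.image_io` defines.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import InputError
from .image_io import BinaryMask, Frame, read_mask, write_mask
import imageio.v3 as iio


@dataclass
class FrameDataset:
    frames: np.ndarray          # (N, H, W, 3) float32 in [0, 1]
    masks: np.ndarray           # (N, H, W) uint8 {0, 1}
    patient_ids: np.ndarray     # (N,) str
    video_ids: np.ndarray       # (N,) str
    t: np.ndarray               # (N,) int, per-video frame index
    corrupted: np.ndarray = None  # (N,) bool, full-frame corruption flags

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.masks = np.asarray(self.masks, dtype=np.uint8)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.video_ids = np.asarray(self.video_ids, dtype=object)
        self.t = np.asarray(self.t, dtype=int)
        if self.corrupted is None:
            self.corrupted = np.zeros(len(self.frames), dtype=bool)
        self.corrupted = np.asarray(self.corrupted, dtype=bool)
        n = len(self.frames)
        for name in ("masks", "patient_ids", "video_ids", "t", "corrupted"):
            if len(getattr(self, name)) != n:
                raise InputError(f"{name} length does not match frame count {n}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def patients(self) -> List[str]:
        return sorted(set(self.patient_ids.tolist()))

    def subset(self, idx) -> "FrameDataset":
        idx = np.asarray(idx)
        return FrameDataset(self.frames[idx], self.masks[idx],
                            self.patient_ids[idx], self.video_ids[idx],
                            self.t[idx], self.corrupted[idx])

    def split_by_patient(self, held_out: Sequence[str]
                         ) -> Tuple["FrameDataset", "FrameDataset"]:
        """Return (rest, held_out) with zero patient overlap."""
        held = set(held_out)
        mask = np.array([p in held for p in self.patient_ids])
        return self.subset(np.where(~mask)[0]), self.subset(np.where(mask)[0])

    def concat(self, other: "FrameDataset") -> "FrameDataset":
        return FrameDataset(
            np.concatenate([self.frames, other.frames]),
            np.concatenate([self.masks, other.masks]),
            np.concatenate([self.patient_ids, other.patient_ids]),
            np.concatenate([self.video_ids, other.video_ids]),
            np.concatenate([self.t, other.t]),
            np.concatenate([self.corrupted, other.corrupted]))

    def triplet_inputs(self) -> np.ndarray:
        """(N, H, W, 9) channelwise-stacked (I(t-1), I(t), I(t+1)) per frame,
        with edge replication at each video's boundaries."""
        out = np.empty(self.frames.shape[:3] + (9,), dtype=np.float32)
        for vid in sorted(set(self.video_ids.tolist())):
            idx = np.where(self.video_ids == vid)[0]
            idx = idx[np.argsort(self.t[idx])]
            n = len(idx)
            for j, i in enumerate(idx):
                left = self.frames[idx[max(j - 1, 0)]]
                right = self.frames[idx[min(j + 1, n - 1)]]
                out[i] = np.concatenate([left, self.frames[i], right], axis=2)
        return out

    def manifest_rows(self) -> List[Dict]:
        return [{"frame": f"{v}/frame_{t:05d}.png",
                 "mask": f"{v}/frame_{t:05d}_mask.png",
                 "video_id": v, "patient_id": p, "t": int(t),
                 "corrupted": int(c)}
                for v, p, t, c in zip(self.video_ids, self.patient_ids,
                                      self.t, self.corrupted)]

    def write(self, out_dir) -> Path:
        """Write PNG frames/masks and ``manifest.csv``; returns the manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = self.manifest_rows()
        for row, frame, mask in zip(rows, self.frames, self.masks):
            fpath = out_dir / row["frame"]
            fpath.parent.mkdir(parents=True, exist_ok=True)
            iio.imwrite(fpath, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
            write_mask(BinaryMask(mask), out_dir / row["mask"])
        manifest = out_dir / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
        return manifest

    @classmethod
    def read(cls, root) -> "FrameDataset":
        """Load a dataset from a directory containing ``manifest.csv``."""
        root = Path(root)
        manifest = root / "manifest.csv"
        if not manifest.exists():
            raise InputError(f"no manifest.csv under {root}")
        frames, masks, pids, vids, ts, corr = [], [], [], [], [], []
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                arr = np.asarray(iio.imread(root / row["frame"]))
                frames.append(arr.astype(np.float32) / 255.0)
                masks.append(read_mask(root / row["mask"]).pixels)
                pids.append(row["patient_id"])
                vids.append(row["video_id"])
                ts.append(int(row["t"]))
                corr.append(bool(int(row.get("corrupted", 0))))
        return cls(np.stack(frames), np.stack(masks), np.array(pids, dtype=object),
                   np.array(vids, dtype=object), np.array(ts), np.array(corr))
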