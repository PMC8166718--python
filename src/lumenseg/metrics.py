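"""Overlap metrics, the Dice loss, aggregation, and model comparison.

Per-frame scoring reduces a predicted/true mask pair to pixel confusion
counts and derives from them

    L_DSC = 1 - 2*TP / (2*TP + FN + FP)
    DSC   = 1 - L_DSC
    Prec  = TP / (TP + FP)
    Rec   = TP / (TP + FN)

Reported numbers are means over frames of per-frame metrics (matching a
per-frame box-plot view of a test video), never pooled-pixel statistics.
Distributions of per-frame DSC are compared across models with the
Kruskal-Wallis rank test.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from .errors import AlignmentError, InputError
from .image_io import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies for one scored frame."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsRecord:
    """Per-frame DSC / precision / recall for one model."""

    dsc: float
    precision: float
    recall: float
    t: int = 0
    model_tag: str = ""


def _as_binary(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels.astype(bool)
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise InputError("mask values must be 0/1")
    return arr.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN between a predicted and a true binary mask."""
    p, g = _as_binary(pred), _as_binary(truth)
    if p.shape != g.shape:
        raise AlignmentError(f"mask shapes differ: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dice_loss(counts: ConfusionCounts, empty_value: float = 0.0) -> float:
    """Dice loss 1 - 2TP/(2TP+FN+FP); both-empty convention is perfect
    agreement (loss ``empty_value``, default 0)."""
    denom = 2 * counts.TP + counts.FN + counts.FP
    if denom == 0:
        return empty_value
    return 1.0 - 2.0 * counts.TP / denom


def dsc(counts: ConfusionCounts, empty_value: float = 1.0) -> float:
    """Dice similarity coefficient, the complement of the Dice loss."""
    denom = 2 * counts.TP + counts.FN + counts.FP
    if denom == 0:
        return empty_value
    return 2.0 * counts.TP / denom


def precision(counts: ConfusionCounts, empty_value: float = 1.0) -> float:
    if counts.TP + counts.FP == 0:
        # nothing predicted: perfect if nothing to find, else 0
        return empty_value if counts.FN == 0 else 0.0
    return counts.TP / (counts.TP + counts.FP)


def recall(counts: ConfusionCounts, empty_value: float = 1.0) -> float:
    if counts.TP + counts.FN == 0:
        return empty_value if counts.FP == 0 else 0.0
    return counts.TP / (counts.TP + counts.FN)


def evaluate_frame(pred, truth, t: int = 0, model_tag: str = "") -> MetricsRecord:
    """Score one frame; empty-empty pairs count as perfect agreement."""
    c = confusion_counts(pred, truth)
    return MetricsRecord(dsc=dsc(c), precision=precision(c), recall=recall(c),
                         t=t, model_tag=model_tag)


@dataclass(frozen=True)
class PairwiseComparison:
    model_a: str
    model_b: str
    statistic: float
    p_value: float
    stars: str


def significance_stars(p: float) -> str:
    """Box-plot annotation convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ModelComparison:
    statistic: float
    p_value: float
    pairwise: List[PairwiseComparison]


def compare_models(per_frame_dsc: Dict[str, Sequence[float]]) -> ModelComparison:
    """Kruskal-Wallis omnibus test on per-frame DSC distributions, plus
    pairwise (two-group) Kruskal-Wallis tests with significance stars."""
    if len(per_frame_dsc) < 2:
        raise InputError("need at least two models to compare")
    for tag, vals in per_frame_dsc.items():
        if len(vals) < 2:
            raise InputError(f"model {tag!r} needs at least two frames")
    groups = {tag: np.asarray(v, dtype=float) for tag, v in per_frame_dsc.items()}

    def kw(samples):
        try:
            h, p = stats.kruskal(*samples)
        except ValueError:  # all values identical across groups
            h, p = 0.0, 1.0
        return float(h), float(p)

    h, p = kw(list(groups.values()))
    pairwise = []
    for a, b in combinations(groups, 2):
        hp, pp = kw([groups[a], groups[b]])
        pairwise.append(PairwiseComparison(a, b, hp, pp, significance_stars(pp)))
    return ModelComparison(h, p, pairwise)


def summarize(records: Sequence[MetricsRecord]) -> Dict[str, Dict[str, float]]:
    """Mean and quartiles of each metric over frames, per model tag."""
    out: Dict[str, Dict[str, float]] = {}
    tags = sorted({r.model_tag for r in records})
    for tag in tags:
        sel = [r for r in records if r.model_tag == tag]
        entry = {"n_frames": len(sel)}
        for name in ("dsc", "precision", "recall"):
            vals = np.array([getattr(r, name) for r in sel], dtype=float)
            entry[f"{name}_mean"] = float(vals.mean())
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])
            entry[f"{name}_q1"] = float(q1)
            entry[f"{name}_median"] = float(q2)
            entry[f"{name}_q3"] = float(q3)
        out[tag] = entry
    return out


def write_report(records: Sequence[MetricsRecord], out_dir,
                 comparison: ModelComparison | None = None) -> None:
    """Emit the per-frame CSV and the JSON summary for an evaluation run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "per_frame_metrics.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "model", "dsc", "precision", "recall"])
        for r in records:
            writer.writerow([r.t, r.model_tag, f"{r.dsc:.6f}",
                             f"{r.precision:.6f}", f"{r.recall:.6f}"])
    summary = {"models": summarize(records)}
    if comparison is not None:
        summary["kruskal_wallis"] = {
            "H": comparison.statistic,
            "p_value": comparison.p_value,
            "pairwise": [asdict(pc) for pc in comparison.pairwise],
        }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


# overlay colors: TP yellow, FP pink, FN blue, TN black
_OVERLAY = {
    "tp": (1.0, 1.0, 0.0),
    "fp": (1.0, 0.41, 0.71),
    "fn": (0.0, 0.0, 1.0),
    "tn": (0.0, 0.0, 0.0),
}


def overlay_image(pred, truth) -> np.ndarray:
    """RGB visualization of per-pixel agreement between pred and truth."""
    p, g = _as_binary(pred), _as_binary(truth)
    if p.shape != g.shape:
        raise AlignmentError("pred/truth shapes differ")
    out = np.zeros(p.shape + (3,), dtype=np.float32)
    out[p & g] = _OVERLAY["tp"]
    out[p & ~g] = _OVERLAY["fp"]
    out[~p & g] = _OVERLAY["fn"]
    return out
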