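"""Run configuration: one YAML file describing data, models, training.

Every CLI command resolves a :class:`RunConfig`, snapshots it (with the
seed) into its run directory, and logs structured JSONL events, so any run
is auditable and repeatable from its artifacts alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .errors import ConfigError

DEFAULTS: Dict = {
    "paths": {"data": "data", "output": "runs"},
    "simulate": {"n_videos": 11, "frames_per_video": 40,
                 "frame_size": [64, 64],
                 "center_frame_corruption": 0.0},
    "model": {"depth": 3, "base_filters": 16, "input_size": 64,
              "use_batch_norm": True,
              "backbone": "resnet50", "min_detection_confidence": 0.7,
              "anchor_scales": [32, 64, 128, 160]},
    "temporal": {"n_k": 8, "activation": "relu"},
    "augment": {"copies_per_frame": 4, "seed": 0},
    "ensemble": {"members": ["m1", "m2", "M1", "M2"], "threshold": 0.5},
    "train": {"lr": 1e-3, "bs": 8, "epochs": 10, "patience": 10,
              "split_ratio": 0.6, "n_folds": 5,
              "learning_rates": [1e-3, 1e-4, 1e-5, 1e-6],
              "batch_sizes": [4, 8, 16],
              "n_k_options": [3, 8, 16]},
    "seed": 0,
}


def _merge(base: Dict, override: Dict) -> Dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    raw: Dict

    @classmethod
    def load(cls, path: Optional[str] = None, overrides: Optional[Dict] = None
             ) -> "RunConfig":
        cfg = DEFAULTS
        if path is not None:
            p = Path(path)
            if not p.exists():
                raise ConfigError(f"config file not found: {p}")
            with open(p) as fh:
                user = yaml.safe_load(fh) or {}
            if not isinstance(user, dict):
                raise ConfigError("config file must contain a YAML mapping")
            cfg = _merge(cfg, user)
        cfg = _merge(cfg, overrides or {})
        rc = cls(cfg)
        rc.validate()
        return rc

    def __getitem__(self, key):
        return self.raw[key]

    def validate(self) -> List[str]:
        """Collect every violation; raise ConfigError listing all of them."""
        problems = []
        if "seed" not in self.raw:
            problems.append("seed is required")
        tr = self.raw.get("train", {})
        if tr.get("epochs", 1) < 1:
            problems.append("train.epochs must be >= 1")
        if not (0 < tr.get("split_ratio", 0.6) < 1):
            problems.append("train.split_ratio must lie in (0, 1)")
        ens = self.raw.get("ensemble", {})
        members = ens.get("members", [])
        if len(members) != len(set(members)):
            problems.append("ensemble.members must be unique")
        if not (0 < ens.get("threshold", 0.5) < 1):
            problems.append("ensemble.threshold must lie in (0, 1)")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))
        return problems

    def make_run_dir(self, command: str) -> Path:
        stamp = time.strftime("%Y%m%d-%H%M%S")
        run_dir = Path(self.raw["paths"]["output"]) / f"{stamp}-{command}"
        run_dir.mkdir(parents=True, exist_ok=True)
        with open(run_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.raw, fh)
        return run_dir


class JsonlLogger:
    """Structured append-only log of run events (params, seed, metrics)."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def log(self, event: str, **payload):
        with open(self.path, "a") as fh:
            fh.write(json.dumps({"time": time.time(), "event": event,
                                 **payload}) + "\n")
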