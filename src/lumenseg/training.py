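"""Training, patient-wise cross-validation, grid search, and ablation.

All members minimize the differentiable soft-Dice loss with Adam.  Model
selection follows mean validation DSC: hyperparameters are searched over a
grid with patient-wise k-fold cross-validation (no patient ever appears on
both sides of a fold), the winning combination is refit on a 60/40
train/validation split of all training-patient frames, and the resulting
checkpoints feed the ensemble and its ablation variants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import yaml

from . import nn
from .core_models import (InstanceSegSpec, ResUNetSpec, SegmentationModel,
                          build_instance_core, build_resunet, resize_frame)
from .dataset import FrameDataset
from .ensemble import EnsembleConfig, binarize, ensemble_predict_arrays, table2_variants
from .errors import (ConfigError, DependencyError, DivergenceError, InputError)
from .metrics import MetricsRecord, compare_models, evaluate_frame
from .temporal_extension import TemporalExtensionSpec, extend_model


@dataclass(frozen=True)
class GridSearchSpace:
    """Hyperparameter grids; model-specific axes may be empty."""

    learning_rates: Tuple[float, ...] = (1e-3, 1e-4, 1e-5, 1e-6)
    batch_sizes: Tuple[int, ...] = (4, 8, 16)
    n_k_options: Tuple[int, ...] = ()           # temporal ResUNet (M1) only
    backbone_options: Tuple[str, ...] = ()      # instance core (m2) only
    confidence_grid: Tuple[float, ...] = ()     # instance core (m2) only

    def __post_init__(self):
        if not self.learning_rates or not self.batch_sizes:
            raise ConfigError("learning_rates and batch_sizes must be non-empty")
        if any(lr <= 0 for lr in self.learning_rates):
            raise ConfigError("learning rates must be positive")
        if any(bs <= 0 for bs in self.batch_sizes):
            raise ConfigError("batch sizes must be positive")

    def combinations(self) -> List[Dict]:
        axes = [("lr", sorted(self.learning_rates)),
                ("bs", sorted(self.batch_sizes))]
        if self.n_k_options:
            axes.append(("n_k", sorted(self.n_k_options)))
        if self.backbone_options:
            axes.append(("backbone", list(self.backbone_options)))
        if self.confidence_grid:
            axes.append(("confidence", sorted(self.confidence_grid)))
        names = [a[0] for a in axes]
        return [dict(zip(names, combo))
                for combo in itertools.product(*[a[1] for a in axes])]


@dataclass(frozen=True)
class FoldAssignment:
    """Patient-wise CV folds: (train patients, validation patients) pairs."""

    folds: Tuple[Tuple[Tuple[str, ...], Tuple[str, ...]], ...]

    def __post_init__(self):
        for train, val in self.folds:
            if set(train) & set(val):
                raise ConfigError("train/validation patients overlap in a fold")


def make_patient_folds(patient_ids: Sequence[str], n_folds: int,
                       seed: int = 0) -> FoldAssignment:
    """Partition patients into k validation groups; with k == #patients this
    is leave-one-patient-out.  Deterministic in seed."""
    patients = sorted(set(patient_ids))
    if n_folds > len(patients):
        raise ConfigError(
            f"cannot make {n_folds} folds from {len(patients)} patients")
    if n_folds < 2:
        raise ConfigError("need at least 2 folds")
    order = list(np.random.default_rng(seed).permutation(patients))
    groups: List[List[str]] = [[] for _ in range(n_folds)]
    for i, pat in enumerate(order):
        groups[i % n_folds].append(pat)
    folds = tuple(
        (tuple(sorted(set(patients) - set(g))), tuple(sorted(g)))
        for g in groups)
    return FoldAssignment(folds)


@dataclass
class TrainResult:
    model: SegmentationModel
    history: Dict[str, List[float]]
    best_epoch: int
    best_val_dsc: float


def _prepare_inputs(ds: FrameDataset, model: SegmentationModel
                    ) -> Tuple[np.ndarray, np.ndarray]:
    x = ds.triplet_inputs() if model.temporal else ds.frames
    y = ds.masks.astype(np.float32)
    if model.input_size is not None and (
            x.shape[1] != model.input_size or x.shape[2] != model.input_size):
        x = np.stack([resize_frame(xi, model.input_size) for xi in x])
        s = model.input_size
        idx_r = (np.arange(s) * y.shape[1] / s).astype(int)
        idx_c = (np.arange(s) * y.shape[2] / s).astype(int)
        y = y[:, idx_r][:, :, idx_c]  # nearest-neighbor mask resize
    return x.astype(np.float32), y[..., None]


def _val_dsc(model: SegmentationModel, x: np.ndarray, y: np.ndarray,
             threshold: float = 0.5) -> float:
    model.eval()
    dscs = []
    for i in range(0, len(x), 16):
        probs = model.forward(nn.Tensor(x[i:i + 16])).data
        pred = probs >= threshold
        g = y[i:i + 16] > 0.5
        for pj, gj in zip(pred, g):
            denom = 2 * np.count_nonzero(pj & gj) + np.count_nonzero(pj ^ gj)
            dscs.append(1.0 if denom == 0
                        else 2 * np.count_nonzero(pj & gj) / denom)
    return float(np.mean(dscs))


def train_model(model: SegmentationModel, train_ds: FrameDataset,
                val_ds: FrameDataset, lr: float, bs: int, epochs: int,
                seed: int = 0, patience: int = 10) -> TrainResult:
    """Minimize soft-Dice with Adam; keep the best-validation-DSC weights.

    Fully seeded: weight init comes with the model, shuffling from ``seed``.
    A zero learning rate leaves the weights untouched (useful as a control).
    Raises :class:`DivergenceError` on a non-finite loss.
    """
    if len(train_ds) == 0:
        raise InputError("training set is empty")
    if lr < 0:
        raise ConfigError("learning rate must be non-negative")
    rng = np.random.default_rng(seed)
    x_tr, y_tr = _prepare_inputs(train_ds, model)
    x_va, y_va = _prepare_inputs(val_ds, model) if len(val_ds) else (None, None)
    opt = nn.Adam(model.parameters(), lr=lr)
    history = {"train_loss": [], "val_loss": [], "val_dsc": []}
    best_state, best_dsc, best_epoch, since_best = None, -1.0, -1, 0
    for epoch in range(epochs):
        model.train()
        perm = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(perm), bs):
            idx = perm[i:i + bs]
            opt.zero_grad()
            probs = model.forward(nn.Tensor(x_tr[idx]))
            loss = nn.soft_dice_loss(probs, y_tr[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {i // bs} "
                    f"(lr={lr}, bs={bs})")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if x_va is not None:
            model.eval()
            probs = np.concatenate(
                [model.forward(nn.Tensor(x_va[i:i + 16])).data
                 for i in range(0, len(x_va), 16)])
            vloss = 1.0 - (2 * (probs * y_va).sum() + 1e-6) / (
                probs.sum() + y_va.sum() + 1e-6)
            vdsc = _val_dsc(model, x_va, y_va)
            history["val_loss"].append(float(vloss))
            history["val_dsc"].append(vdsc)
            if vdsc > best_dsc:
                best_dsc, best_epoch, since_best = vdsc, epoch, 0
                best_state = model.state_dict()
            else:
                since_best += 1
                if since_best >= patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model, history, best_epoch, best_dsc)


ModelFactory = Callable[[Dict, int], SegmentationModel]


@dataclass
class GridSearchResult:
    best_params: Dict
    cv_table: List[Dict]  # one row per (combination, fold)

    def mean_dsc_by_combo(self) -> Dict[Tuple, float]:
        combos: Dict[Tuple, List[float]] = {}
        for row in self.cv_table:
            key = tuple(sorted((k, v) for k, v in row.items()
                               if k not in ("fold", "val_dsc")))
            combos.setdefault(key, []).append(row["val_dsc"])
        return {k: float(np.mean(v)) for k, v in combos.items()}


def grid_search(space: GridSearchSpace, folds: FoldAssignment,
                model_factory: ModelFactory, dataset: FrameDataset,
                epochs: int = 10, seed: int = 0,
                patience: int = 10) -> GridSearchResult:
    """Train every grid combination on every fold; select the combination
    with the highest mean validation DSC.  Ties break toward the smaller
    learning rate, then the smaller batch size."""
    combos = space.combinations()
    cv_table: List[Dict] = []
    for ci, combo in enumerate(combos):
        for fi, (train_pats, val_pats) in enumerate(folds.folds):
            train_idx = [i for i, p in enumerate(dataset.patient_ids)
                         if p in train_pats]
            val_idx = [i for i, p in enumerate(dataset.patient_ids)
                       if p in val_pats]
            if not train_idx:
                raise ConfigError(f"fold {fi} has an empty training set")
            model = model_factory(combo, seed + 1000 * ci)
            result = train_model(model, dataset.subset(train_idx),
                                 dataset.subset(val_idx), combo["lr"],
                                 combo["bs"], epochs,
                                 seed=seed + 1000 * ci + fi,
                                 patience=patience)
            cv_table.append({**combo, "fold": fi,
                             "val_dsc": result.best_val_dsc})
    means = []
    for combo in combos:
        vals = [row["val_dsc"] for row in cv_table
                if all(row[k] == v for k, v in combo.items())]
        means.append((float(np.mean(vals)), combo))
    best = max(means, key=lambda mv: (
        mv[0], -mv[1]["lr"], -mv[1]["bs"]))  # ties: smaller lr, smaller bs
    return GridSearchResult(best_params=best[1], cv_table=cv_table)


def select_from_cv_table(cv_table: List[Dict]) -> Dict:
    """Re-derive the winning combination from an emitted CV table alone."""
    combos: Dict[Tuple, List[float]] = {}
    for row in cv_table:
        key = tuple(sorted((k, v) for k, v in row.items()
                           if k not in ("fold", "val_dsc")))
        combos.setdefault(key, []).append(row["val_dsc"])
    scored = [(float(np.mean(v)), dict(k)) for k, v in combos.items()]
    best = max(scored, key=lambda mv: (mv[0], -mv[1]["lr"], -mv[1]["bs"]))
    return best[1]


def split_frames(dataset: FrameDataset, ratio: float = 0.6, seed: int = 0
                 ) -> Tuple[FrameDataset, FrameDataset]:
    """Frame-random train/validation split stratified by video."""
    if not (0.0 < ratio < 1.0):
        raise ConfigError("split ratio must lie strictly between 0 and 1 "
                          "(validation frames are needed for checkpointing)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for vid in sorted(set(dataset.video_ids.tolist())):
        idx = np.where(dataset.video_ids == vid)[0]
        perm = rng.permutation(idx)
        cut = int(round(ratio * len(idx)))
        train_idx.extend(perm[:cut])
        val_idx.extend(perm[cut:])
    return dataset.subset(np.array(sorted(train_idx))), \
        dataset.subset(np.array(sorted(val_idx)))


def final_fit(members: Dict[str, SegmentationModel],
              best_params: Dict[str, Dict], dataset: FrameDataset,
              split_ratio: float = 0.6, epochs: int = 10, seed: int = 0
              ) -> Dict[str, TrainResult]:
    """Refit each member with its selected hyperparameters on a 60/40
    frame split of all training-patient frames."""
    missing = set(members) - set(best_params)
    if missing:
        raise ConfigError(f"missing selected hyperparameters for {sorted(missing)}; "
                          "run the grid search first")
    train_ds, val_ds = split_frames(dataset, split_ratio, seed)
    results = {}
    for tag, model in members.items():
        params = best_params[tag]
        results[tag] = train_model(model, train_ds, val_ds, params["lr"],
                                   params["bs"], epochs, seed=seed)
    return results


def predict_dataset(model: SegmentationModel, ds: FrameDataset) -> np.ndarray:
    """(N, H, W) probability maps for every frame of a dataset."""
    x = ds.triplet_inputs() if model.temporal else ds.frames
    if model.input_size is not None and (
            x.shape[1] != model.input_size or x.shape[2] != model.input_size):
        from .core_models import resize_map
        native = x.shape[1:3]
        xr = np.stack([resize_frame(xi, model.input_size) for xi in x])
        probs = model.predict_proba(xr)
        return np.stack([resize_map(pm, native) for pm in probs])
    return model.predict_proba(x)


def evaluate_model_on(ds: FrameDataset, probs: np.ndarray, model_tag: str,
                      threshold: float = 0.5) -> List[MetricsRecord]:
    return [evaluate_frame((pm >= threshold).astype(np.uint8), gm,
                           t=int(t), model_tag=model_tag)
            for pm, gm, t in zip(probs, ds.masks, ds.t)]


@dataclass
class AblationReport:
    records: List[MetricsRecord]
    summary: Dict[str, float]             # config tag -> mean DSC
    comparison: "object"                  # ModelComparison over single models

    def configurations(self) -> List[str]:
        return sorted(self.summary)


def run_ablation(models: Dict[str, SegmentationModel], test_ds: FrameDataset,
                 threshold: float = 0.5) -> AblationReport:
    """Evaluate each single member, the four two-member ensemble variants,
    and the full four-member ensemble, all through the same averaging path."""
    required = ("m1", "m2", "M1", "M2")
    missing = [t for t in required if t not in models]
    if missing:
        raise DependencyError(f"missing trained members: {missing}")
    probs = {tag: predict_dataset(models[tag], test_ds) for tag in required}
    configs: List[EnsembleConfig] = (
        [EnsembleConfig((t,)) for t in required]
        + list(table2_variants())
        + [EnsembleConfig(required)])
    records: List[MetricsRecord] = []
    summary: Dict[str, float] = {}
    for cfg in configs:
        tag = "+".join(cfg.members)
        fused = ensemble_predict_arrays([probs[m] for m in cfg.members])
        recs = evaluate_model_on(test_ds, fused, tag, cfg.binarize_threshold)
        records.extend(recs)
        summary[tag] = float(np.mean([r.dsc for r in recs]))
    singles_dsc = {t: [r.dsc for r in records if r.model_tag == t]
                   for t in required}
    comparison = compare_models(singles_dsc)
    return AblationReport(records, summary, comparison)


def _spec_to_dict(obj) -> Dict:
    return {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(obj).items()}


def save_checkpoint(model: SegmentationModel, path) -> Path:
    """Serialize weights (.npz) with the architecture spec alongside (.yaml)."""
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    info = {"model_tag": model.model_tag, "class": type(model).__name__,
            "input_channels": int(model.input_channels)}
    if hasattr(model, "core"):  # extended model
        info["core_class"] = type(model.core).__name__
        info["core_spec"] = _spec_to_dict(model.core.spec)
        info["core_input_channels"] = int(model.core.input_channels)
        info["tspec"] = _spec_to_dict(model.tspec)
    else:
        info["spec"] = _spec_to_dict(model.spec)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(info, fh)
    return path


def _build_from_info(info: Dict) -> SegmentationModel:
    def mkspec(cls, d):
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**d)

    cls = info["class"]
    if cls == "ResUNet":
        return build_resunet(mkspec(ResUNetSpec, info["spec"]),
                             input_channels=info.get("input_channels", 3))
    if cls == "InstanceSegCore":
        return build_instance_core(mkspec(InstanceSegSpec, info["spec"]))
    if cls == "ExtendedModel":
        tspec = mkspec(TemporalExtensionSpec, info["tspec"])
        if info["core_class"] == "ResUNet":
            core_spec = mkspec(ResUNetSpec, info["core_spec"])
        else:
            core_spec = mkspec(InstanceSegSpec, info["core_spec"])
        return extend_model(core_spec, tspec)
    raise ConfigError(f"unknown model class in checkpoint: {cls}")


def load_checkpoint(path, model: SegmentationModel | None = None
                    ) -> SegmentationModel:
    """Rebuild a model from its spec YAML and load the saved weights.

    Pass ``model`` to load into an existing compatible architecture instead.
    """
    path = Path(path).with_suffix(".npz")
    if not path.exists():
        raise DependencyError(f"missing checkpoint: {path}")
    if model is None:
        with open(path.with_suffix(".yaml")) as fh:
            info = yaml.safe_load(fh)
        model = _build_from_info(info)
        model.model_tag = info.get("model_tag", model.model_tag)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
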