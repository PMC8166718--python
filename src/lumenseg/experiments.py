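"""End-to-end study pipelines on the synthetic fixture.

These functions wire the generator, training loop, temporal extension and
ensemble into the package's reference experiments: desk-scale learnability
of the residual U-Net, the temporal-information recovery effect (a
multi-frame model segmenting frames whose own content is destroyed, from
the neighbors alone), the ensemble ablation suite, and a type-I-error check
of the Kruskal-Wallis comparison.  Problem sizes are chosen so each
experiment runs in minutes on one CPU; every source of randomness derives
from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict

import numpy as np
from scipy import stats

from .core_models import InstanceSegSpec, ResUNetSpec, build_instance_core, build_resunet
from .dataset import FrameDataset
from .synthetic_data import SyntheticSceneParams, generate_dataset
from .temporal_extension import TemporalExtensionSpec, extend_model
from .training import (evaluate_model_on, predict_dataset, run_ablation,
                       split_frames, train_model)

TEST_PATIENT = "P6"  # the four-video synthetic patient is held out for testing


def _fixture(seed: int, frames_per_video: int = 42,
             corruption_rate: float = 0.0) -> FrameDataset:
    """Default 6-patient / 11-video fixture at 64x64, artifact-light."""
    params = SyntheticSceneParams(
        frame_size=(64, 64),
        artifact_rates={"center_frame_corruption": corruption_rate})
    return generate_dataset(n_videos=11, frames_per_video=frames_per_video,
                            params=params, seed=seed)


def _resunet_spec() -> ResUNetSpec:
    return ResUNetSpec(depth=3, base_filters=16, input_shape=(64, 64, 3))


def learnability_experiment(seed: int = 0, epochs: int = 10,
                            lr: float = 1e-3, bs: int = 8) -> Dict[str, float]:
    """Train m1 on the training patients (~300 frames) and score the
    held-out synthetic patient.  Returns mean test DSC/Prec/Rec."""
    ds = _fixture(seed)
    train_pool, test_ds = ds.split_by_patient([TEST_PATIENT])
    train_ds, val_ds = split_frames(train_pool, 0.6, seed=seed)
    model = build_resunet(_resunet_spec(), seed=seed)
    result = train_model(model, train_ds, val_ds, lr=lr, bs=bs, epochs=epochs,
                         seed=seed, patience=5)
    probs = predict_dataset(result.model, test_ds)
    records = evaluate_model_on(test_ds, probs, "m1")
    return {
        "test_dsc": float(np.mean([r.dsc for r in records])),
        "test_precision": float(np.mean([r.precision for r in records])),
        "test_recall": float(np.mean([r.recall for r in records])),
        "best_val_dsc": result.best_val_dsc,
        "n_train": len(train_ds), "n_test": len(test_ds),
    }


def temporal_recovery_experiment(seed: int = 0, epochs: int = 10,
                                 lr: float = 1e-3, bs: int = 8,
                                 corruption_rate: float = 0.3,
                                 n_k: int = 8) -> Dict[str, float]:
    """Corrupt isolated center frames to noise and compare m1 vs M1.

    The single-frame model can only guess on a destroyed frame; the
    triplet model sees the intact neighbors.  Both are trained identically
    on the same corrupted fixture; DSC is reported on the corrupted test
    frames, where the temporal pathway is the only source of information.
    """
    ds = _fixture(seed, corruption_rate=corruption_rate)
    train_pool, test_ds = ds.split_by_patient([TEST_PATIENT])
    train_ds, val_ds = split_frames(train_pool, 0.6, seed=seed)

    m1 = build_resunet(_resunet_spec(), seed=seed)
    r1 = train_model(m1, train_ds, val_ds, lr, bs, epochs, seed=seed,
                     patience=5)
    M1 = extend_model(_resunet_spec(), TemporalExtensionSpec(n_k=n_k),
                      seed=seed)
    R1 = train_model(M1, train_ds, val_ds, lr, bs, epochs, seed=seed,
                     patience=5)

    corrupted = test_ds.subset(np.where(test_ds.corrupted)[0])
    clean = test_ds.subset(np.where(~test_ds.corrupted)[0])
    out: Dict[str, float] = {"n_corrupted_test": len(corrupted),
                             "n_clean_test": len(clean)}
    for tag, res, sub in (("m1_corrupted", r1, corrupted),
                          ("M1_corrupted", R1, corrupted),
                          ("m1_clean", r1, clean),
                          ("M1_clean", R1, clean)):
        # the corrupted split needs triplet context from the full test video
        if res.model.temporal:
            probs_all = predict_dataset(res.model, test_ds)
            sel = test_ds.corrupted if "corrupted" in tag else ~test_ds.corrupted
            probs = probs_all[sel]
        else:
            probs = predict_dataset(res.model, sub)
        recs = evaluate_model_on(sub, probs, tag)
        out[tag + "_dsc"] = float(np.mean([r.dsc for r in recs]))
    out["recovery_gain"] = out["M1_corrupted_dsc"] - out["m1_corrupted_dsc"]
    return out


def ablation_experiment(seed: int = 0, epochs: int = 4, lr: float = 1e-3,
                        bs: int = 8, frames_per_video: int = 12,
                        n_k: int = 8) -> Dict[str, float]:
    """Train all four members briefly on a small fixture and run the full
    ablation suite (4 singles, 4 pairs, full ensemble)."""
    ds = _fixture(seed, frames_per_video=frames_per_video)
    train_pool, test_ds = ds.split_by_patient([TEST_PATIENT])
    train_ds, val_ds = split_frames(train_pool, 0.6, seed=seed)
    ispec = InstanceSegSpec(min_detection_confidence=0.5, input_size=64)
    members = {
        "m1": build_resunet(_resunet_spec(), seed=seed),
        "m2": build_instance_core(ispec, seed=seed + 1),
        "M1": extend_model(_resunet_spec(), TemporalExtensionSpec(n_k=n_k),
                           seed=seed + 2),
        "M2": extend_model(ispec, TemporalExtensionSpec(n_k=3), seed=seed + 3),
    }
    for tag, model in members.items():
        members[tag] = train_model(model, train_ds, val_ds, lr, bs, epochs,
                                   seed=seed, patience=epochs).model
    report = run_ablation(members, test_ds)
    out = dict(report.summary)
    out["n_test"] = len(test_ds)
    return out


def kruskal_type1_experiment(seed: int = 0, n_groups: int = 3,
                             n_per_group: int = 30,
                             n_replicates: int = 1000,
                             alpha: float = 0.05) -> float:
    """Empirical rejection rate of the Kruskal-Wallis test under the null
    (all groups drawn from one distribution)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        groups = [rng.normal(size=n_per_group) for _ in range(n_groups)]
        _, p = stats.kruskal(*groups)
        rejections += p < alpha
    return rejections / n_replicates
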