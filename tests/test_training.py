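"""Folds, training loop, grid search, final fit, ablation, checkpoints."""

import numpy as np
import pytest

from lumenseg.augmentation import augment_dataset
from lumenseg.core_models import InstanceSegSpec, ResUNetSpec, build_instance_core, build_resunet
from lumenseg.errors import ConfigError, DependencyError, InputError
from lumenseg.synthetic_data import generate_dataset
from lumenseg.temporal_extension import TemporalExtensionSpec, extend_model
from lumenseg.training import (FoldAssignment, GridSearchSpace, final_fit,
                               grid_search, load_checkpoint,
                               make_patient_folds, predict_dataset,
                               run_ablation, save_checkpoint,
                               select_from_cv_table, split_frames,
                               train_model)

from conftest import tiny_scene_params


def _small_model(seed=0):
    return build_resunet(ResUNetSpec(depth=2, base_filters=8,
                                     input_shape=(16, 16, 3)), seed=seed)


class TestFolds:
    def test_five_patients_five_folds_is_lopo(self):
        folds = make_patient_folds(["P1", "P2", "P3", "P4", "P6"], 5, seed=0)
        val_sets = [set(v) for _, v in folds.folds]
        assert all(len(v) == 1 for v in val_sets)
        assert set.union(*val_sets) == {"P1", "P2", "P3", "P4", "P6"}

    def test_each_patient_validates_exactly_once(self):
        folds = make_patient_folds([f"P{i}" for i in range(7)], 3, seed=1)
        seen = [p for _, val in folds.folds for p in val]
        assert sorted(seen) == sorted(set(seen))

    def test_more_folds_than_patients_rejected(self):
        with pytest.raises(ConfigError):
            make_patient_folds(["P1", "P2"], 6, seed=0)

    def test_deterministic_in_seed(self):
        a = make_patient_folds([f"P{i}" for i in range(6)], 3, seed=9)
        b = make_patient_folds([f"P{i}" for i in range(6)], 3, seed=9)
        assert a.folds == b.folds

    def test_overlapping_fold_rejected(self):
        with pytest.raises(ConfigError):
            FoldAssignment(((("P1",), ("P1",)),))


class TestTrainModel:
    def test_zero_lr_leaves_weights(self, tiny_dataset):
        model = _small_model()
        before = {k: v.copy() for k, v in model.state_dict().items()
                  if v.ndim > 1}
        train, val = split_frames(tiny_dataset, 0.6, seed=0)
        result = train_model(model, train, val, lr=0.0, bs=4, epochs=1, seed=0)
        assert len(result.history["train_loss"]) == 1
        for k, v in before.items():
            np.testing.assert_array_equal(model.state_dict()[k], v)

    def test_deterministic_history(self, tiny_dataset):
        train, val = split_frames(tiny_dataset, 0.6, seed=0)
        h1 = train_model(_small_model(1), train, val, 1e-3, 4, 2,
                         seed=5).history
        h2 = train_model(_small_model(1), train, val, 1e-3, 4, 2,
                         seed=5).history
        assert h1 == h2

    def test_empty_train_set_rejected(self, tiny_dataset):
        with pytest.raises(InputError):
            train_model(_small_model(), tiny_dataset.subset(np.array([], int)),
                        tiny_dataset, 1e-3, 4, 1)

    def test_best_checkpoint_tracks_val_dsc(self, tiny_dataset):
        train, val = split_frames(tiny_dataset, 0.6, seed=0)
        result = train_model(_small_model(2), train, val, 1e-3, 4, 3, seed=0)
        assert result.best_val_dsc == max(result.history["val_dsc"])
        assert result.history["val_dsc"][result.best_epoch] \
            == result.best_val_dsc


class TestSplitFrames:
    def test_sixty_forty(self):
        ds = generate_dataset(2, 50, tiny_scene_params(), seed=0,
                              patient_layout=("PA", "PB"))
        train, val = split_frames(ds, 0.6, seed=0)
        assert len(train) == 60 and len(val) == 40

    def test_ratio_one_rejected(self, tiny_dataset):
        with pytest.raises(ConfigError):
            split_frames(tiny_dataset, 1.0)

    def test_no_frame_lost_or_duplicated(self, tiny_dataset):
        train, val = split_frames(tiny_dataset, 0.6, seed=3)
        assert len(train) + len(val) == len(tiny_dataset)


class TestGridSearch:
    def _run(self, space, tiny_dataset, **kw):
        folds = make_patient_folds(tiny_dataset.patient_ids, 2, seed=0)
        return grid_search(space, folds,
                           lambda combo, s: _small_model(s),
                           tiny_dataset, epochs=1, seed=0, **kw)

    def test_singleton_space(self, tiny_dataset):
        res = self._run(GridSearchSpace((1e-3,), (4,)), tiny_dataset)
        assert res.best_params == {"lr": 1e-3, "bs": 4}
        assert len(res.cv_table) == 2  # 1 combination x 2 folds

    def test_grid_cardinality(self):
        space = GridSearchSpace((1e-3, 1e-4, 1e-5, 1e-6), (4, 8, 16))
        assert len(space.combinations()) == 12

    def test_selection_rederivable_from_table(self, tiny_dataset):
        res = self._run(GridSearchSpace((1e-3, 1e-2), (4,)), tiny_dataset)
        assert select_from_cv_table(res.cv_table) == res.best_params

    def test_tie_breaks_toward_smaller_lr(self):
        table = [{"lr": 1e-3, "bs": 4, "fold": 0, "val_dsc": 0.5},
                 {"lr": 1e-4, "bs": 4, "fold": 0, "val_dsc": 0.5}]
        assert select_from_cv_table(table)["lr"] == 1e-4

    def test_empty_space_rejected(self):
        with pytest.raises(ConfigError):
            GridSearchSpace((), (4,))


class TestPatientLeakage:
    def test_augmented_copies_follow_their_patient(self, tiny_dataset):
        aug = augment_dataset(tiny_dataset, copies_per_frame=1, seed=0)
        folds = make_patient_folds(aug.patient_ids, 2, seed=0)
        for train_pats, val_pats in folds.folds:
            in_val = [p for p in aug.patient_ids if p in val_pats]
            in_train = [p for p in aug.patient_ids if p in train_pats]
            assert set(in_val).isdisjoint(set(in_train))
            assert len(in_val) + len(in_train) == len(aug)


class TestFinalFitAndAblation:
    def test_final_fit_requires_params(self, tiny_dataset):
        with pytest.raises(ConfigError):
            final_fit({"m1": _small_model()}, {}, tiny_dataset)

    def test_final_fit_returns_model_per_member(self, tiny_dataset):
        members = {"m1": _small_model(0), "m2": _small_model(1)}
        params = {t: {"lr": 1e-3, "bs": 4} for t in members}
        results = final_fit(members, params, tiny_dataset, epochs=1, seed=0)
        assert set(results) == {"m1", "m2"}

    def test_ablation_reports_nine_configurations(self, tiny_dataset):
        rspec = ResUNetSpec(depth=2, base_filters=8, input_shape=(16, 16, 3))
        ispec = InstanceSegSpec(min_detection_confidence=0.5, input_size=16)
        models = {"m1": build_resunet(rspec, 0),
                  "m2": build_instance_core(ispec, 1),
                  "M1": extend_model(rspec, TemporalExtensionSpec(n_k=4), 2),
                  "M2": extend_model(ispec, TemporalExtensionSpec(n_k=3), 3)}
        report = run_ablation(models, tiny_dataset)
        assert len(report.summary) == 9
        assert len(report.records) == 9 * len(tiny_dataset)
        assert "m1+m2+M1+M2" in report.summary

    def test_ablation_missing_member_rejected(self, tiny_dataset):
        with pytest.raises(DependencyError):
            run_ablation({"m1": _small_model()}, tiny_dataset)


class TestCheckpoints:
    @pytest.mark.parametrize("builder", [
        lambda: _small_model(4),
        lambda: build_instance_core(InstanceSegSpec(input_size=16), 4),
        lambda: extend_model(ResUNetSpec(depth=2, base_filters=8,
                                         input_shape=(16, 16, 3)),
                             TemporalExtensionSpec(n_k=4), 4),
    ])
    def test_roundtrip_preserves_predictions(self, tmp_path, builder, rng):
        model = builder()
        x = rng.random((2, 16, 16, model.input_channels)).astype(np.float32)
        before = model.predict_proba(x)
        path = save_checkpoint(model, tmp_path / "ckpt.npz")
        restored = load_checkpoint(path)
        np.testing.assert_allclose(restored.predict_proba(x), before,
                                   atol=1e-6)

    def test_missing_checkpoint_raises(self, tmp_path):
        with pytest.raises(DependencyError):
            load_checkpoint(tmp_path / "none.npz")
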