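"""Fold plans, batch construction, and the two-stage training loops."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from flimcontrast.model import EncoderConfig, HeadConfig, PixelClassifier
from flimcontrast.preprocess import PixelDataset
from flimcontrast.train import (AblationFlags, TrainConfig, make_fold_plan,
                                preprocess_cohort, pretrain_contrastive,
                                run_experiment, stratified_batches,
                                train_multitask)


@dataclass
class FakePatient:
    patient_id: int
    diagnosis: str


def _roster(n_benign, n_malignant):
    return ([FakePatient(i, "benign") for i in range(n_benign)]
            + [FakePatient(n_benign + i, "SCC") for i in range(n_malignant)])


SMOKE_CONFIG = TrainConfig(pre_lr=1e-3, mt_lr=1e-3, pre_batch_size=128,
                           pre_epochs=2, mt_batch_size=128, mt_epochs=2,
                           monitor_subsample=400, seed=0)
SMOKE_ENCODER = EncoderConfig(input_dim=150, hidden_widths=(32, 16, 8),
                              bottleneck=16)


@pytest.fixture(scope="module")
def pp_cohort(small_cohort):
    _, patients = small_cohort
    return preprocess_cohort(patients, median_window=3, snr_threshold=2.0,
                             per_channel_length=50)


@pytest.fixture(scope="module")
def train_dev(pp_cohort):
    pids = [p.patient_id for p in pp_cohort.patients]
    return pp_cohort.dataset_for(pids[:4]), pp_cohort.dataset_for(pids[4:])


class TestFoldPlan:
    def test_exact_stratification_20_patients(self):
        plan = make_fold_plan(_roster(10, 10), n_folds=10, seed=0)
        benign = {p.patient_id for p in _roster(10, 10)[:10]}
        for fold in range(10):
            members = plan.patients_in(fold)
            assert len(members) == 2
            assert sum(1 for m in members if m in benign) == 1

    def test_rotation_covers_every_patient_exactly_once(self):
        plan = make_fold_plan(_roster(7, 6), n_folds=10, seed=3)
        seen = []
        for run in plan.runs:
            seen += plan.patients_in(run.test_fold)
        assert sorted(seen) == list(range(13))

    def test_no_split_overlap_within_run(self):
        plan = make_fold_plan(_roster(8, 8), n_folds=8, seed=1)
        for run in plan.runs:
            train, dev, test = plan.split(run)
            assert not (set(train) & set(dev))
            assert not (set(train) & set(test))
            assert not (set(dev) & set(test))
            assert sorted(train + dev + test) == list(range(16))

    def test_fold_sizes_differ_by_at_most_one_per_class(self):
        plan = make_fold_plan(_roster(13, 9), n_folds=5, seed=4)
        benign = set(range(13))
        for cls_members in (benign, set(range(13, 22))):
            counts = [len([p for p in plan.patients_in(f) if p in cls_members])
                      for f in range(5)]
            assert max(counts) - min(counts) <= 1

    def test_seed_determinism(self):
        a = make_fold_plan(_roster(6, 6), n_folds=4, seed=9)
        b = make_fold_plan(_roster(6, 6), n_folds=4, seed=9)
        assert a.fold_of_patient == b.fold_of_patient

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(_roster(2, 2), n_folds=10, seed=0)


class TestStratifiedBatches:
    def test_batches_partition_dataset(self, rng):
        labels = rng.integers(0, 3, 1000)
        batches = stratified_batches(labels, 128, rng)
        flat = np.concatenate(batches)
        assert sorted(flat.tolist()) == list(range(1000))

    def test_every_batch_contains_every_class(self, rng):
        labels = np.repeat([0, 1, 2], [500, 300, 200])
        for idx in stratified_batches(labels, 100, rng):
            assert set(labels[idx]) == {0, 1, 2}


class TestPretrain:
    def test_history_bookkeeping_and_clipping(self, train_dev):
        train_ds, dev_ds = train_dev
        model = PixelClassifier(SMOKE_ENCODER, seed=0)
        _, history = pretrain_contrastive(model, train_ds, SMOKE_CONFIG,
                                          dev_dataset=dev_ds)
        assert len(history) == SMOKE_CONFIG.pre_epochs + 1  # incl. init row
        assert history.epoch.tolist() == [-1, 0, 1]
        clipped = history.clipped_norm_max.dropna()
        assert (clipped <= SMOKE_CONFIG.grad_clip + 1e-9).all()
        assert np.isfinite(history.dev_silhouette).all()

    def test_seed_determinism(self, train_dev):
        train_ds, dev_ds = train_dev
        histories = []
        for _ in range(2):
            model = PixelClassifier(SMOKE_ENCODER, seed=0)
            _, h = pretrain_contrastive(model, train_ds, SMOKE_CONFIG,
                                        dev_dataset=dev_ds)
            histories.append(h)
        pd.testing.assert_frame_equal(histories[0], histories[1])

    def test_missing_class_rejected(self, train_dev):
        train_ds, _ = train_dev
        only_two = train_ds.subset(train_ds.contrastive != 2)
        model = PixelClassifier(SMOKE_ENCODER, seed=0)
        with pytest.raises(ValueError):
            pretrain_contrastive(model, only_two, SMOKE_CONFIG)


class TestMultitask:
    def test_history_and_determinism(self, train_dev):
        train_ds, dev_ds = train_dev
        histories = []
        for _ in range(2):
            model = PixelClassifier(SMOKE_ENCODER, seed=1)
            _, h = train_multitask(model, train_ds, SMOKE_CONFIG,
                                   dev_dataset=dev_ds)
            histories.append(h)
        assert len(histories[0]) == SMOKE_CONFIG.mt_epochs
        pd.testing.assert_frame_equal(histories[0], histories[1])

    def test_single_task_ablation_leaves_delineation_head_untrained(
            self, train_dev):
        train_ds, dev_ds = train_dev
        model = PixelClassifier(SMOKE_ENCODER, seed=1)
        before = [w.copy() for w in model.head_delin.params()]
        train_multitask(model, train_ds, SMOKE_CONFIG, dev_dataset=dev_ds,
                        ablation=AblationFlags(multitask=False))
        after = model.head_delin.params()
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_frozen_encoder_unchanged(self, train_dev):
        train_ds, dev_ds = train_dev
        from dataclasses import replace
        model = PixelClassifier(SMOKE_ENCODER, seed=1)
        before = [w.copy() for w in model.encoder.params()]
        train_multitask(model, train_ds,
                        replace(SMOKE_CONFIG, freeze_encoder=True),
                        dev_dataset=dev_ds)
        for b, a in zip(before, model.encoder.params()):
            assert np.array_equal(b, a)


class TestRunExperiment:
    def test_smoke_two_trials_two_folds(self, pp_cohort):
        result = run_experiment(pp_cohort, SMOKE_CONFIG, n_trials=2,
                                n_folds=2, encoder_config=SMOKE_ENCODER,
                                seed=5)
        assert len(result.run_reports) == 4
        assert set(result.runs.trial) == {0, 1}
        # aggregate equals the arithmetic mean of the run rows
        col = "delineation_lh_accuracy"
        assert result.overall[col] == pytest.approx(result.runs[col].mean())

    def test_all_ablations_off_is_single_task_classifier(self, pp_cohort):
        flags = AblationFlags(clustering_pretrain=False,
                              separation_pretrain=False,
                              adaptive_clustering=False, consistency=False,
                              multitask=False, adaptive_beta=False)
        assert not flags.pretrain
        result = run_experiment(pp_cohort, SMOKE_CONFIG, ablation=flags,
                                n_trials=1, n_folds=2,
                                encoder_config=SMOKE_ENCODER, seed=5)
        assert all(r.pretrain_history is None for r in result.run_reports)
        assert len(result.run_reports) == 2

    def test_no_patient_leaks_across_split(self, pp_cohort):
        patients = pp_cohort.patients
        plan = make_fold_plan(patients, n_folds=3, seed=2)
        for run in plan.runs:
            train, dev, test = plan.split(run)
            train_px = pp_cohort.dataset_for(train).patient_id
            test_px = pp_cohort.dataset_for(test).patient_id
            assert not (set(train_px) & set(test_px))
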