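"""Two-stage training protocol and patient-level cross-validation.

Stage 1 pre-trains the encoder with the contrastive clustering/separation
loss on stratified pixel batches (Adam, lr 1e-5, batch 512, gradient
clipping at 0.25, 10 epochs at full scale), monitoring the silhouette
score of a training subsample each epoch to drive the adaptive clustering
weight, and selecting the checkpoint with the best development-set
silhouette. Stage 2 adds the two task heads and optimizes the multitask
loss (Adam, lr 1e-5, batch 256, 5 epochs), with balanced sample weights
from the training distribution and checkpoint selection by the
development set's mean pixel-level balanced accuracy over the tasks.

Cross-validation splits at the *patient* level: a patient's lesion and
healthy images always share a fold, so no patient spans the train/dev/
test boundary within a run. One trial = one random stratified 10-fold
split; its 10 runs rotate the test fold (the next 2 folds are the
development set); independent trials re-randomize the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import MALIGNANT_DIAGNOSES, PatientSample
from .evaluate import aggregate_image, balanced_accuracy, compute_metrics, \
    silhouette_score
from .losses import (balanced_class_weights, contrastive_loss_and_grad,
                     adaptive_alpha, cross_entropy, multitask_loss,
                     sample_weights_from)
from .model import EncoderConfig, HeadConfig, PixelClassifier
from .nn import DTYPE, Adam, clip_global_norm
from .preprocess import PixelDataset, compute_snr_mask, image_to_training_pixels, \
    median_filter

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AblationFlags:
    """Toggles for the component-contribution analysis.

    ``multitask=False`` trains the diagnosis head alone (single-task);
    with both pretraining terms off the pipeline reduces to the plain
    classifier.
    """

    clustering_pretrain: bool = True
    separation_pretrain: bool = True
    adaptive_clustering: bool = True   # silhouette-driven alpha schedule
    consistency: bool = True
    multitask: bool = True
    adaptive_beta: bool = True

    @property
    def pretrain(self) -> bool:
        return self.clustering_pretrain or self.separation_pretrain


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for both stages."""

    pre_lr: float = 1e-5
    pre_batch_size: int = 512
    pre_epochs: int = 10
    grad_clip: float = 0.25
    mt_lr: float = 1e-5
    mt_batch_size: int = 256
    mt_epochs: int = 5
    alpha0: float = 1.0
    epsilon: float = 1e-8
    monitor_subsample: int = 10_000
    freeze_encoder: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.pre_lr, self.mt_lr) <= 0:
            raise ValueError("learning rates must be positive")
        if min(self.pre_batch_size, self.mt_batch_size) < 1:
            raise ValueError("batch sizes must be positive")
        if min(self.pre_epochs, self.mt_epochs) < 1:
            raise ValueError("epochs must be >= 1")
        if self.grad_clip <= 0:
            raise ValueError("gradient clip must be positive")


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunSplit:
    test_fold: int
    dev_folds: tuple[int, ...]
    train_folds: tuple[int, ...]


@dataclass
class FoldPlan:
    """Patient-level, diagnosis-stratified fold assignment for one trial."""

    n_folds: int
    fold_of_patient: dict[int, int]
    runs: list[RunSplit]
    seed: int

    def patients_in(self, folds) -> list[int]:
        folds = set(np.atleast_1d(folds).tolist())
        return sorted(p for p, f in self.fold_of_patient.items() if f in folds)

    def split(self, run: RunSplit):
        return (self.patients_in(run.train_folds),
                self.patients_in(run.dev_folds),
                self.patients_in(run.test_fold))


def _rotation_runs(n_folds: int) -> list[RunSplit]:
    runs = []
    n_dev = 2 if n_folds >= 4 else 1
    for r in range(n_folds):
        dev = tuple((r + 1 + k) % n_folds for k in range(n_dev))
        train = tuple(f for f in range(n_folds) if f != r and f not in dev)
        if not train:
            # degenerate smoke configurations (n_folds == 2): train on the
            # development fold
            train = dev
        runs.append(RunSplit(test_fold=r, dev_folds=dev, train_folds=train))
    return runs


def make_fold_plan(patients: list[PatientSample], n_folds: int = 10,
                   seed: int = 0) -> FoldPlan:
    """Stratified-by-diagnosis assignment of patients to folds.

    Both of a patient's images inherit the patient's fold. Within each
    diagnosis class, shuffled patients are dealt round-robin, so fold
    sizes differ by at most one patient per class. Runs rotate the test
    fold; the following folds form the development set.
    """
    if n_folds < 2:
        raise ValueError("need at least two folds")
    if len(patients) < n_folds:
        raise ValueError(
            f"{len(patients)} patients cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    fold_of: dict[int, int] = {}
    for malignant in (False, True):
        pids = sorted(p.patient_id for p in patients
                      if (p.diagnosis in MALIGNANT_DIAGNOSES) == malignant)
        order = rng.permutation(len(pids))
        start = rng.integers(n_folds)  # rotate so small classes spread fairly
        for i, j in enumerate(order):
            fold_of[pids[j]] = int((start + i) % n_folds)
    return FoldPlan(n_folds=n_folds, fold_of_patient=fold_of,
                    runs=_rotation_runs(n_folds), seed=seed)


# ---------------------------------------------------------------------------
# batch construction
# ---------------------------------------------------------------------------

def stratified_batches(labels: np.ndarray, batch_size: int,
                       rng: np.random.Generator) -> list[np.ndarray]:
    """Class-stratified batch index lists covering the dataset once.

    Each class's shuffled indices are split proportionally across batches,
    so every batch contains every class (hence, after patient shuffling,
    typically several patients per class) whenever the class has at least
    as many pixels as there are batches.
    """
    n = len(labels)
    n_batches = max(1, int(np.ceil(n / batch_size)))
    parts = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        parts.append(np.array_split(rng.permutation(idx), n_batches))
    return [np.concatenate([p[i] for p in parts]) for i in range(n_batches)]


def _subsample(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    if n <= k:
        return np.arange(n)
    return rng.choice(n, size=k, replace=False)


# ---------------------------------------------------------------------------
# stage 1: contrastive pre-training
# ---------------------------------------------------------------------------

def pretrain_contrastive(model: PixelClassifier, dataset: PixelDataset,
                         config: TrainConfig,
                         dev_dataset: PixelDataset | None = None,
                         ablation: AblationFlags = AblationFlags(),
                         required_classes=(0, 1, 2)):
    """Train the encoder with the contrastive loss; select by dev silhouette.

    Returns ``(best_state, history)`` where ``history`` is a per-epoch
    DataFrame (epoch -1 records the untrained initialization) and
    ``best_state`` restores the selected checkpoint via
    ``model.set_state``. The model is left at the selected checkpoint.
    """
    present = set(np.unique(dataset.contrastive).tolist())
    missing = set(required_classes) - present
    if missing:
        raise ValueError(f"pretraining dataset is missing classes {sorted(missing)}")

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.encoder.params(), lr=config.pre_lr)
    alpha = config.alpha0

    monitor_idx = _subsample(rng, len(dataset), config.monitor_subsample)
    dev = dev_dataset if dev_dataset is not None and len(dev_dataset) else dataset
    dev_idx = _subsample(rng, len(dev), config.monitor_subsample)

    def monitored_silhouette(ds: PixelDataset, idx: np.ndarray) -> float:
        # batch statistics: the embedding the loss sees, well defined
        # before the running BN estimates are warmed up
        emb = model.embed(ds.X[idx], batch_stats=True)
        return silhouette_score(emb, ds.contrastive[idx]).score

    history = []
    init_dev_sil = monitored_silhouette(dev, dev_idx)
    history.append({"epoch": -1, "l_clust": np.nan, "l_sep": np.nan,
                    "l_contr": np.nan, "alpha": alpha,
                    "train_silhouette": monitored_silhouette(dataset, monitor_idx),
                    "dev_silhouette": init_dev_sil,
                    "grad_norm_max": np.nan, "clipped_norm_max": np.nan})
    best = (init_dev_sil, model.get_state(), -1)

    for epoch in range(config.pre_epochs):
        sums = np.zeros(3)
        grad_norms = []
        batches = stratified_batches(dataset.contrastive,
                                     config.pre_batch_size, rng)
        for idx in batches:
            tap, _ = model.encoder.forward(dataset.X[idx], training=True)
            report, grad = contrastive_loss_and_grad(
                tap, dataset.contrastive[idx], dataset.patient_id[idx],
                alpha=alpha, epsilon=config.epsilon,
                use_clustering=ablation.clustering_pretrain,
                use_separation=ablation.separation_pretrain,
                adaptive=ablation.adaptive_beta)
            model.encoder.backward(grad_tap=grad.astype(DTYPE))
            grads = model.encoder.grads()
            grad_norms.append(clip_global_norm(grads, config.grad_clip))
            optimizer.step(grads)
            sums += (report.l_clust, report.l_sep, report.l_contr)

        train_sil = monitored_silhouette(dataset, monitor_idx)
        dev_sil = monitored_silhouette(dev, dev_idx)
        if ablation.adaptive_clustering:
            alpha = adaptive_alpha(train_sil, config.alpha0)
        history.append({"epoch": epoch,
                        "l_clust": sums[0] / len(batches),
                        "l_sep": sums[1] / len(batches),
                        "l_contr": sums[2] / len(batches),
                        "alpha": alpha,
                        "train_silhouette": train_sil,
                        "dev_silhouette": dev_sil,
                        "grad_norm_max": max(grad_norms),
                        "clipped_norm_max": min(max(grad_norms),
                                                config.grad_clip)})
        if dev_sil > best[0]:
            best = (dev_sil, model.get_state(), epoch)

    model.set_state(best[1])
    history = pd.DataFrame(history)
    history.attrs["selected_epoch"] = best[2]
    history.attrs["init_dev_silhouette"] = init_dev_sil
    history.attrs["best_dev_silhouette"] = best[0]
    return best[1], history


# ---------------------------------------------------------------------------
# stage 2: multitask training
# ---------------------------------------------------------------------------

def _dev_score(model: PixelClassifier, ds: PixelDataset, idx: np.ndarray,
               multitask: bool) -> float:
    diag_pred, delin_pred = model.predict(ds.X[idx])
    diag_ba = balanced_accuracy(diag_pred, ds.diagnosis[idx])
    if not multitask:
        return diag_ba
    delin_ba = balanced_accuracy(delin_pred, ds.delineation[idx])
    return (diag_ba + delin_ba) / 2


def train_multitask(model: PixelClassifier, dataset: PixelDataset,
                    config: TrainConfig,
                    dev_dataset: PixelDataset | None = None,
                    ablation: AblationFlags = AblationFlags()):
    """Joint (or single-task) classifier training on a pretrained encoder.

    The encoder keeps updating (joint fine-tuning) unless
    ``config.freeze_encoder``; sample weights are the balanced class
    weights of the training distribution per task. Returns
    ``(best_state, history)`` and leaves the model at the selected
    checkpoint.
    """
    rng = np.random.default_rng(config.seed + 1)
    params = [] if config.freeze_encoder else list(model.encoder.params())
    params += model.head_diag.params()
    if ablation.multitask:
        params += model.head_delin.params()
    optimizer = Adam(params, lr=config.mt_lr)

    diag_w = balanced_class_weights(dataset.diagnosis)
    delin_w = balanced_class_weights(dataset.delineation)

    dev = dev_dataset if dev_dataset is not None and len(dev_dataset) else dataset
    dev_idx = _subsample(rng, len(dev), config.monitor_subsample)

    history = []
    best = (_dev_score(model, dev, dev_idx, ablation.multitask),
            model.get_state(), -1)
    for epoch in range(config.mt_epochs):
        order = rng.permutation(len(dataset))
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, len(order), config.mt_batch_size):
            idx = order[start:start + config.mt_batch_size]
            _, feats, logits_diag, logits_delin = model.forward(
                dataset.X[idx], training=True)
            if ablation.multitask:
                report, g_diag, g_delin = multitask_loss(
                    logits_diag, logits_delin,
                    dataset.diagnosis[idx], dataset.delineation[idx],
                    dataset.contrastive[idx],
                    diag_weights=sample_weights_from(dataset.diagnosis[idx], diag_w),
                    delin_weights=sample_weights_from(dataset.delineation[idx], delin_w),
                    use_consistency=ablation.consistency)
                sums += (report.ce_diag, report.ce_delin, report.l_reg,
                         report.l_mt)
                g_feat = model.head_diag.backward(g_diag.astype(DTYPE)) \
                    + model.head_delin.backward(g_delin.astype(DTYPE))
            else:
                ce, g_diag = cross_entropy(
                    logits_diag, dataset.diagnosis[idx],
                    sample_weights_from(dataset.diagnosis[idx], diag_w))
                sums += (ce, 0.0, 0.0, ce)
                g_feat = model.head_diag.backward(g_diag.astype(DTYPE))
            if not config.freeze_encoder:
                model.encoder.backward(grad_features=g_feat)
            grads = [] if config.freeze_encoder else list(model.encoder.grads())
            grads += model.head_diag.grads()
            if ablation.multitask:
                grads += model.head_delin.grads()
            optimizer.step(grads)
            n_batches += 1

        score = _dev_score(model, dev, dev_idx, ablation.multitask)
        history.append({"epoch": epoch,
                        "ce_diag": sums[0] / n_batches,
                        "ce_delin": sums[1] / n_batches,
                        "l_reg": sums[2] / n_batches,
                        "l_mt": sums[3] / n_batches,
                        "dev_score": score})
        if score > best[0]:
            best = (score, model.get_state(), epoch)

    model.set_state(best[1])
    history = pd.DataFrame(history)
    history.attrs["selected_epoch"] = best[2]
    history.attrs["best_dev_score"] = best[0]
    return best[1], history


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedCohort:
    """Cached per-image pixel datasets plus patient metadata."""

    patients: list[PatientSample]
    pixelsets: dict[tuple[int, str], PixelDataset]  # (patient_id, tissue)

    def dataset_for(self, patient_ids) -> PixelDataset:
        parts = [self.pixelsets[(pid, tissue)]
                 for pid in patient_ids for tissue in ("lesion", "healthy")]
        return PixelDataset.concat([p for p in parts if len(p)])


def preprocess_cohort(patients: list[PatientSample], median_window: int = 3,
                      snr_threshold: float = 2.0,
                      per_channel_length: int = 300) -> PreprocessedCohort:
    """Median-filter, mask and pixel-preprocess every image of a cohort."""
    pixelsets = {}
    for patient in patients:
        for tissue, image in (("lesion", patient.lesion),
                              ("healthy", patient.healthy)):
            filtered = median_filter(image, median_window)
            filtered.snr_mask = compute_snr_mask(filtered, snr_threshold)
            pixelsets[(patient.patient_id, tissue)] = \
                image_to_training_pixels(filtered, per_channel_length)
    return PreprocessedCohort(patients=patients, pixelsets=pixelsets)


@dataclass
class RunReport:
    trial: int
    run: int
    metrics: dict[str, "object"]        # task -> MetricsReport
    image_predictions: pd.DataFrame
    pretrain_history: pd.DataFrame | None
    multitask_history: pd.DataFrame

    def flat(self) -> dict:
        row = {"trial": self.trial, "run": self.run}
        for task, rep in self.metrics.items():
            for key, val in rep.to_dict().items():
                row[f"{task}_{key}"] = val
        return row


def evaluate_run(model: PixelClassifier, cohort: PreprocessedCohort,
                 test_pids: list[int], trial: int = 0, run: int = 0,
                 pretrain_history=None, multitask_history=None) -> RunReport:
    """Image-level evaluation of a trained model on held-out patients.

    Diagnosis metrics use lesion images only; margin delineation is
    evaluated for both clinical use cases: malignant vs healthy (M-H) and
    any-lesion vs healthy (L-H).
    """
    rows = []
    for pid in test_pids:
        patient = next(p for p in cohort.patients if p.patient_id == pid)
        for tissue in ("lesion", "healthy"):
            ds = cohort.pixelsets[(pid, tissue)]
            if len(ds) == 0:
                logger.warning("patient %s %s image fully masked; skipped",
                               pid, tissue)
                continue
            diag_pred, delin_pred = model.predict(ds.X)
            rows.append({
                "patient_id": pid, "tissue_type": tissue,
                "malignant": patient.diagnosis in MALIGNANT_DIAGNOSES,
                "diag_true": int(ds.diagnosis[0]),
                "delin_true": int(ds.delineation[0]),
                "diag_pred": aggregate_image(diag_pred, image_id=f"{pid}-{tissue}").label,
                "delin_pred": aggregate_image(delin_pred, image_id=f"{pid}-{tissue}").label,
                "diag_positive_fraction": float(np.mean(diag_pred == 1)),
                "delin_positive_fraction": float(np.mean(delin_pred == 1)),
            })
    frame = pd.DataFrame(rows)
    lesions = frame[frame.tissue_type == "lesion"]
    mh = frame[(frame.tissue_type == "healthy")
               | ((frame.tissue_type == "lesion") & frame.malignant)]
    metrics = {
        "diagnosis": compute_metrics(lesions.diag_pred, lesions.diag_true),
        "delineation_mh": compute_metrics(mh.delin_pred, mh.delin_true),
        "delineation_lh": compute_metrics(frame.delin_pred, frame.delin_true),
    }
    return RunReport(trial=trial, run=run, metrics=metrics,
                     image_predictions=frame,
                     pretrain_history=pretrain_history,
                     multitask_history=multitask_history)


@dataclass
class ExperimentResult:
    run_reports: list[RunReport]
    runs: pd.DataFrame = field(init=False)
    trial_means: pd.DataFrame = field(init=False)
    overall: pd.Series = field(init=False)

    def __post_init__(self):
        self.runs = pd.DataFrame([r.flat() for r in self.run_reports])
        numeric = self.runs.drop(columns=["run"])
        self.trial_means = numeric.groupby("trial").mean()
        self.overall = numeric.drop(columns=["trial"]).mean()

    def pooled_image_predictions(self) -> pd.DataFrame:
        return pd.concat([r.image_predictions for r in self.run_reports],
                         ignore_index=True)


def run_experiment(cohort: PreprocessedCohort, config: TrainConfig,
                   ablation: AblationFlags = AblationFlags(),
                   n_trials: int = 1, n_folds: int = 10,
                   runs_per_trial: int | None = None,
                   encoder_config: EncoderConfig = EncoderConfig(),
                   head_config: HeadConfig = HeadConfig(),
                   seed: int = 0) -> ExperimentResult:
    """Full cross-validated experiment with optional ablations.

    ``runs_per_trial`` truncates the fold rotation (scaled-down studies);
    ``None`` runs all ``n_folds`` rotations per trial.
    """
    ss = np.random.SeedSequence(seed)
    reports = []
    for trial, trial_ss in enumerate(ss.spawn(n_trials)):
        plan_seed, *run_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                                 for s in trial_ss.spawn(n_folds + 1)]
        plan = make_fold_plan(cohort.patients, n_folds=n_folds, seed=plan_seed)
        runs = plan.runs if runs_per_trial is None else plan.runs[:runs_per_trial]
        for run_idx, run in enumerate(runs):
            train_pids, dev_pids, test_pids = plan.split(run)
            train_ds = cohort.dataset_for(train_pids)
            dev_ds = cohort.dataset_for(dev_pids)
            run_config = replace(config, seed=run_seeds[run_idx])
            model = PixelClassifier(encoder_config, head_config,
                                    seed=run_seeds[run_idx])
            pre_hist = None
            if ablation.pretrain:
                _, pre_hist = pretrain_contrastive(
                    model, train_ds, run_config, dev_dataset=dev_ds,
                    ablation=ablation)
            _, mt_hist = train_multitask(model, train_ds, run_config,
                                         dev_dataset=dev_ds, ablation=ablation)
            reports.append(evaluate_run(model, cohort, test_pids,
                                        trial=trial, run=run_idx,
                                        pretrain_history=pre_hist,
                                        multitask_history=mt_hist))
            logger.info("trial %d run %d: diagnosis avg %s", trial, run_idx,
                        reports[-1].metrics["diagnosis"].average)
    return ExperimentResult(run_reports=reports)
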