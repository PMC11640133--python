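"""Evaluation: silhouette scoring, pixel-to-image aggregation, metrics.

The silhouette score S = mean over samples of (B - A) / max(A, B), where A
is a sample's mean Euclidean distance to all other points of its class and
B its mean distance to the points of the *next nearest* cluster (the other
class minimizing that mean). It monitors clustering quality during
contrastive pre-training; S is in [-1, 1] and negative values indicate
wrong assignments.

Image-level predictions aggregate pixel labels with a 50% majority rule
(exact ties go to the positive — lesion/malignant — class, the clinically
conservative choice). Classification metrics are reported as percentages
derived from image-level confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist


class DegenerateTestError(ValueError):
    """Paired test undefined (zero variance of the differences)."""


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

@dataclass
class SilhouetteReport:
    score: float              # mean silhouette S in [-1, 1]
    per_sample: np.ndarray    # per-sample s values
    a: np.ndarray             # mean intra-class distances
    b: np.ndarray             # mean distances to the next nearest cluster


def silhouette_score(embeddings: np.ndarray, labels) -> SilhouetteReport:
    """Mean silhouette with Euclidean distances.

    Samples in singleton clusters score 0 (no within-class distances
    exist), as do samples with A = B = 0.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(labels):
        raise ValueError("embeddings must be (n, d) aligned with labels")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("silhouette requires at least two classes")
    if len(X) < 2:
        raise ValueError("silhouette requires at least two samples")

    n = len(X)
    d = cdist(X, X)
    a = np.zeros(n)
    b = np.full(n, np.inf)
    counts = {int(c): int(np.sum(labels == c)) for c in classes}
    for c in classes:
        in_c = labels == c
        d_to_c = d[:, in_c]
        # intra-class: exclude self-distance (0 on the diagonal)
        if counts[int(c)] > 1:
            a[in_c] = d_to_c[in_c].sum(axis=1) / (counts[int(c)] - 1)
        b[~in_c] = np.minimum(b[~in_c], d_to_c[~in_c].mean(axis=1))

    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = denom > 0
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    # singleton clusters score 0 by convention
    singleton = np.isin(labels, [c for c in classes if counts[int(c)] == 1])
    s[singleton] = 0.0
    return SilhouetteReport(score=float(s.mean()), per_sample=s, a=a, b=b)


# ---------------------------------------------------------------------------
# aggregation and metrics
# ---------------------------------------------------------------------------

@dataclass
class ImagePrediction:
    image_id: str
    label: int                # image-level predicted class
    positive_fraction: float  # fraction of pixels predicted positive
    n_pixels: int


def aggregate_image(pixel_predictions: np.ndarray, positive_class: int = 1,
                    negative_class: int = 0,
                    image_id: str = "") -> ImagePrediction:
    """Majority vote over a image's unmasked pixels with a 50% threshold.

    An exact 50/50 tie is assigned to the positive (lesion/malignant)
    class.
    """
    preds = np.asarray(pixel_predictions)
    if preds.size == 0:
        raise ValueError("cannot aggregate an image with no unmasked pixels")
    frac = float(np.mean(preds == positive_class))
    label = positive_class if frac >= 0.5 else negative_class
    return ImagePrediction(image_id=image_id, label=label,
                           positive_fraction=frac, n_pixels=preds.size)


@dataclass
class MetricsReport:
    """Confusion counts and percentage metrics at the image level.

    Ratios with a zero denominator are reported as ``None`` (absent), not
    as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    accuracy: float | None
    average: float | None  # (sensitivity + specificity) / 2

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "tn", "fn", "sensitivity", "specificity",
                 "precision", "f1", "accuracy", "average")}


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(predictions, truths, positive_class: int = 1) -> MetricsReport:
    """Sensitivity/specificity/precision/F1/accuracy from confusion counts."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.size == 0 or predictions.shape != truths.shape:
        raise ValueError("need non-empty, aligned predictions and truths")
    pos_p = predictions == positive_class
    pos_t = truths == positive_class
    tp = int(np.sum(pos_p & pos_t))
    fp = int(np.sum(pos_p & ~pos_t))
    fn = int(np.sum(~pos_p & pos_t))
    tn = int(np.sum(~pos_p & ~pos_t))

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    f1 = (None if prec is None or sens is None or prec + sens == 0
          else 2 * prec * sens / (prec + sens))
    acc = _ratio(tp + tn, tp + tn + fp + fn)
    avg = None if sens is None or spec is None else (sens + spec) / 2
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                         specificity=spec, precision=prec, f1=f1,
                         accuracy=acc, average=avg)


def balanced_accuracy(predictions, truths, positive_class: int = 1) -> float:
    """Mean of sensitivity and specificity on the [0, 1] scale."""
    report = compute_metrics(predictions, truths, positive_class)
    if report.average is None:
        # only one truth class present: fall back to recall of that class
        present = report.sensitivity if report.sensitivity is not None \
            else report.specificity
        return present / 100.0
    return report.average / 100.0


# ---------------------------------------------------------------------------
# significance testing
# ---------------------------------------------------------------------------

def paired_one_tailed_t(x, y) -> tuple[float, float]:
    """Paired t-test on d = x - y, one-tailed for mean(d) > 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    d = x - y
    if np.var(d, ddof=1) == 0:
        raise DegenerateTestError("differences have zero variance")
    res = stats.ttest_rel(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# 2-D embedding snapshots
# ---------------------------------------------------------------------------

def embed_2d_snapshot(model, images, per_channel_length: int = 300,
                      max_pixels_per_image: int = 400, seed: int = 0):
    """Per-image mean 2-D embeddings plus the pixel-level silhouette.

    Requires the visualization configuration (2-unit bottleneck). Returns
    a DataFrame with one row per image (patient id, contrastive class,
    tissue type, x, y) — the plotting payload for embedding-space figures —
    and the :class:`SilhouetteReport` over the sampled pixel embeddings.
    """
    from .preprocess import image_to_training_pixels

    if model.encoder_config.bottleneck != 2:
        raise ValueError("embed_2d_snapshot requires a 2-unit bottleneck")
    rng = np.random.default_rng(seed)
    rows, embs, labels = [], [], []
    for image in images:
        ds = image_to_training_pixels(image, per_channel_length)
        if len(ds) == 0:
            continue
        take = rng.permutation(len(ds))[:max_pixels_per_image]
        emb = model.embed(ds.X[take])
        rows.append({
            "patient_id": image.patient_id,
            "class_label": int(ds.contrastive[0]),
            "tissue_type": image.tissue_type,
            "x": float(emb[:, 0].mean()),
            "y": float(emb[:, 1].mean()),
        })
        embs.append(emb)
        labels.append(ds.contrastive[take])
    payload = pd.DataFrame(rows)
    report = silhouette_score(np.concatenate(embs), np.concatenate(labels))
    return payload, report
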