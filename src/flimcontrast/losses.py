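"""Contrastive and multitask loss functions with analytic gradients.

The contrastive objective drives patient normalization: within a batch,
each class's *anchor* is its mean embedding, each patient's mean embedding
is a *positive* for its own class and a *negative* for every other class.
The clustering term pulls same-class patient means toward their anchor;
the separation term (subtracted, hence maximized) pushes other-class
patient means away:

    L_contr = L_clust - L_sep
    L_clust = sum_c alpha_c sum_{p in c} ||a_c - m_p||^2
    L_sep   = sum_c sum_{c' != c} beta_{c,c'} sum_{p in c'} ||a_c - m_p||^2

Adaptive weights: beta_{c,c'} = 1 / dist(a_c, a_c')^2 (squared Euclidean
distance between class means), normalized to sum to one within each anchor
class, so poorly separated pairs receive more separation pressure; alpha
decays linearly with the silhouette score so clustering pressure relaxes
as the embedding organizes, preventing collapse.

The multitask stage optimizes L_MT = CE_diag + CE_delin + L_reg, where
L_reg is a consistency cross-entropy penalizing contradictory head
predictions (a malignant sample called malignant by the diagnosis head
must be "lesion" to the delineation head; a healthy sample called healthy
by the delineation head cannot be "malignant" to the diagnosis head).

Class-label conventions used throughout the package:
  contrastive (3-class): 0 = healthy, 1 = benign, 2 = malignant
  delineation head:      0 = healthy, 1 = lesion
  diagnosis head:        0 = benign-side (healthy or benign), 1 = malignant
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.utils.class_weight import compute_class_weight

logger = logging.getLogger(__name__)

HEALTHY, BENIGN, MALIGNANT = 0, 1, 2
DELIN_HEALTHY, DELIN_LESION = 0, 1
DIAG_BENIGN_SIDE, DIAG_MALIGNANT = 0, 1

#: Distance guard for adaptive separation weights (coincident class means).
DEFAULT_EPSILON = 1e-8


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

@dataclass
class PatientGroup:
    patient_id: int
    class_label: int
    mean: np.ndarray      # (d,) mean embedding of this patient's batch pixels
    indices: np.ndarray   # pixel row indices in the batch
    n_pixels: int


@dataclass
class ClassAnchors:
    """Per-batch class anchors and per-(class, patient) mean embeddings."""

    classes: np.ndarray                      # sorted class labels present
    anchors: dict[int, np.ndarray]           # class -> pixel-weighted mean
    class_indices: dict[int, np.ndarray]     # class -> pixel row indices
    groups: list[PatientGroup]
    n: int
    dim: int

    def groups_of(self, class_label: int) -> list[PatientGroup]:
        return [g for g in self.groups if g.class_label == class_label]

    def n_pos_patients(self, class_label: int) -> int:
        return len(self.groups_of(class_label))

    def n_neg_patients(self, class_label: int) -> int:
        return sum(1 for g in self.groups if g.class_label != class_label)


def build_anchors(embeddings: np.ndarray, class_labels: np.ndarray,
                  patient_ids: np.ndarray) -> ClassAnchors:
    """Class anchors (pixel-weighted class means) and patient means.

    Classes absent from the batch are simply omitted; the anchor of a class
    equals the pixel-count-weighted mean of its patient means by
    construction.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    class_labels = np.asarray(class_labels)
    patient_ids = np.asarray(patient_ids)
    if embeddings.ndim != 2 or embeddings.shape[0] < 1:
        raise ValueError("embeddings must be a non-empty (n, d) array")
    if not (len(class_labels) == len(patient_ids) == len(embeddings)):
        raise ValueError("labels and patient ids must align with embeddings")

    classes = np.unique(class_labels)
    anchors, class_indices, groups = {}, {}, []
    for c in classes:
        idx_c = np.flatnonzero(class_labels == c)
        anchors[int(c)] = embeddings[idx_c].mean(axis=0)
        class_indices[int(c)] = idx_c
        for p in np.unique(patient_ids[idx_c]):
            idx = idx_c[patient_ids[idx_c] == p]
            groups.append(PatientGroup(
                patient_id=int(p), class_label=int(c),
                mean=embeddings[idx].mean(axis=0),
                indices=idx, n_pixels=len(idx),
            ))
    return ClassAnchors(classes=classes, anchors=anchors,
                        class_indices=class_indices, groups=groups,
                        n=len(embeddings), dim=embeddings.shape[1])


# ---------------------------------------------------------------------------
# adaptive weights
# ---------------------------------------------------------------------------

def _as_alpha_dict(alpha, classes) -> dict[int, float]:
    if np.isscalar(alpha):
        return {int(c): float(alpha) for c in classes}
    return {int(c): float(alpha[int(c)]) for c in classes}


def adaptive_beta(anchors: ClassAnchors,
                  epsilon: float = DEFAULT_EPSILON) -> dict[tuple[int, int], float]:
    """Separation weights beta_{anchor, negative} = 1 / dist^2, normalized.

    ``dist^2`` is the squared Euclidean distance between the two class
    anchors, floored at ``epsilon``; within each anchor class the weights
    are normalized to sum to one, so a poorly separated pair dominates its
    anchor's separation pressure.
    """
    if len(anchors.classes) < 2:
        raise ValueError("adaptive beta needs at least two classes in the batch")
    beta: dict[tuple[int, int], float] = {}
    for c in anchors.classes:
        raw = {}
        for c_neg in anchors.classes:
            if c_neg == c:
                continue
            d2 = float(np.sum((anchors.anchors[int(c)] - anchors.anchors[int(c_neg)]) ** 2))
            raw[int(c_neg)] = 1.0 / max(d2, epsilon)
        total = sum(raw.values())
        for c_neg, b in raw.items():
            beta[(int(c), c_neg)] = b / total
    return beta


def static_beta(anchors: ClassAnchors) -> dict[tuple[int, int], float]:
    """Uniform separation weights, normalized within each anchor class."""
    beta = {}
    for c in anchors.classes:
        negs = [int(c2) for c2 in anchors.classes if c2 != c]
        for c_neg in negs:
            beta[(int(c), c_neg)] = 1.0 / len(negs)
    return beta


def adaptive_alpha(silhouette: float, alpha0: float = 1.0) -> float:
    """Clustering weight alpha = alpha0 * (1 - clamp(S, 0, 1)).

    Monotone non-increasing in the silhouette score S: full clustering
    pressure while the embedding is unorganized (S <= 0), none at perfect
    clustering (S = 1).
    """
    if not np.isfinite(silhouette):
        raise ValueError("silhouette score must be finite")
    return alpha0 * (1.0 - float(np.clip(silhouette, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# contrastive losses
# ---------------------------------------------------------------------------

def clustering_loss(anchors: ClassAnchors, alpha) -> float:
    """L_clust: alpha-weighted squared anchor-to-patient-mean distances."""
    alpha_d = _as_alpha_dict(alpha, anchors.classes)
    total = 0.0
    for c in anchors.classes:
        a = anchors.anchors[int(c)]
        total += alpha_d[int(c)] * sum(
            float(np.sum((a - g.mean) ** 2)) for g in anchors.groups_of(int(c))
        )
    return total


def separation_loss(anchors: ClassAnchors, beta: dict[tuple[int, int], float]) -> float:
    """L_sep: beta-weighted squared distances to other-class patient means."""
    if len(anchors.classes) < 2:
        logger.warning("separation loss over a single-class batch is 0 "
                       "(no negative patients exist)")
        return 0.0
    total = 0.0
    for c in anchors.classes:
        a = anchors.anchors[int(c)]
        for g in anchors.groups:
            if g.class_label == int(c):
                continue
            total += beta[(int(c), g.class_label)] * float(np.sum((a - g.mean) ** 2))
    return total


@dataclass
class ContrastiveLossReport:
    l_clust: float
    l_sep: float
    l_contr: float
    alpha: dict[int, float]
    beta: dict[tuple[int, int], float]
    per_class_clust: dict[int, float] = field(default_factory=dict)
    per_pair_sep: dict[tuple[int, int], float] = field(default_factory=dict)


def contrastive_total(l_clust: float, l_sep: float, alpha=None, beta=None,
                      **extra) -> ContrastiveLossReport:
    """L_contr = L_clust - L_sep (separation is maximized, hence subtracted)."""
    return ContrastiveLossReport(
        l_clust=float(l_clust), l_sep=float(l_sep),
        l_contr=float(l_clust) - float(l_sep),
        alpha=alpha or {}, beta=beta or {}, **extra)


def contrastive_loss_and_grad(embeddings: np.ndarray, class_labels: np.ndarray,
                              patient_ids: np.ndarray, alpha,
                              beta: dict[tuple[int, int], float] | None = None,
                              epsilon: float = DEFAULT_EPSILON,
                              use_clustering: bool = True,
                              use_separation: bool = True,
                              adaptive: bool = True):
    """Full contrastive loss with its gradient w.r.t. the embeddings.

    ``beta`` defaults to the adaptive (``adaptive=True``) or uniform scheme
    computed from the batch anchors; weights are treated as constants
    (no gradient flows through the weighting).  Ablation flags zero out
    either term.  Returns ``(ContrastiveLossReport, grad)`` with ``grad``
    of the same shape as ``embeddings``.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    anchors = build_anchors(embeddings, class_labels, patient_ids)
    alpha_d = _as_alpha_dict(alpha, anchors.classes)
    multi_class = len(anchors.classes) >= 2
    if beta is None and multi_class:
        beta = adaptive_beta(anchors, epsilon) if adaptive else static_beta(anchors)
    beta = beta or {}

    grad = np.zeros_like(embeddings)
    l_clust = 0.0
    per_class_clust: dict[int, float] = {}
    if use_clustering:
        for c in anchors.classes:
            c = int(c)
            a = anchors.anchors[c]
            n_c = len(anchors.class_indices[c])
            d_anchor = np.zeros(anchors.dim)
            term = 0.0
            for g in anchors.groups_of(c):
                diff = a - g.mean
                term += float(np.sum(diff ** 2))
                d_anchor += 2.0 * alpha_d[c] * diff
                grad[g.indices] += (-2.0 * alpha_d[c] / g.n_pixels) * diff
            per_class_clust[c] = alpha_d[c] * term
            l_clust += per_class_clust[c]
            grad[anchors.class_indices[c]] += d_anchor / n_c

    l_sep = 0.0
    per_pair_sep: dict[tuple[int, int], float] = {}
    if use_separation and multi_class:
        grad_sep = np.zeros_like(embeddings)
        for c in anchors.classes:
            c = int(c)
            a = anchors.anchors[c]
            n_c = len(anchors.class_indices[c])
            d_anchor = np.zeros(anchors.dim)
            for g in anchors.groups:
                if g.class_label == c:
                    continue
                b = beta[(c, g.class_label)]
                diff = a - g.mean
                term = b * float(np.sum(diff ** 2))
                per_pair_sep[(c, g.class_label)] = \
                    per_pair_sep.get((c, g.class_label), 0.0) + term
                l_sep += term
                d_anchor += 2.0 * b * diff
                grad_sep[g.indices] += (-2.0 * b / g.n_pixels) * diff
            grad_sep[anchors.class_indices[c]] += d_anchor / n_c
        grad -= grad_sep
    elif use_separation and not multi_class:
        logger.warning("single-class batch: separation term skipped")

    report = contrastive_total(l_clust, l_sep, alpha=alpha_d, beta=beta,
                               per_class_clust=per_class_clust,
                               per_pair_sep=per_pair_sep)
    return report, grad


# ---------------------------------------------------------------------------
# cross-entropy machinery
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray,
                  sample_weights: np.ndarray | None = None):
    """Weighted-mean cross-entropy and its gradient w.r.t. the logits.

    The reduction divides by the sum of the sample weights (unit weights
    give the plain mean), so balanced class weights leave a balanced
    batch's loss scale unchanged.
    """
    n = len(logits)
    p = softmax(np.asarray(logits, dtype=np.float64))
    targets = np.asarray(targets)
    if sample_weights is None:
        sample_weights = np.ones(n)
    w_sum = float(sample_weights.sum())
    nll = -np.log(np.clip(p[np.arange(n), targets], 1e-300, None))
    loss = float((sample_weights * nll).sum() / w_sum)
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    grad *= (sample_weights / w_sum)[:, None]
    return loss, grad


def balanced_class_weights(labels) -> dict[int, float]:
    """scikit-learn "balanced" weights: n_total / (n_classes * n_c)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot compute class weights from an empty label list")
    classes = np.unique(labels)
    weights = compute_class_weight("balanced", classes=classes, y=labels)
    return {int(c): float(w) for c, w in zip(classes, weights)}


def sample_weights_from(labels, class_weights: dict[int, float]) -> np.ndarray:
    return np.array([class_weights[int(y)] for y in labels])


# ---------------------------------------------------------------------------
# consistency regularizer and multitask total
# ---------------------------------------------------------------------------

def consistency_loss_and_grad(diag_logits: np.ndarray, delin_logits: np.ndarray,
                              contrastive_labels: np.ndarray):
    """Cross-entropy penalty on contradictory head predictions.

    Two contradiction patterns contribute, selected by the *other* head's
    predicted class (selection is by argmax and does not backpropagate
    through the selecting head):

    * ground-truth malignant samples that the diagnosis head calls
      malignant: the delineation head is pushed toward "lesion";
    * ground-truth healthy samples that the delineation head calls
      healthy: the diagnosis head is pushed toward its benign side.

    The loss is averaged over contributing samples and is 0 when none
    contribute.  Returns ``(loss, grad_diag, grad_delin)``.
    """
    contrastive_labels = np.asarray(contrastive_labels)
    diag_pred = np.argmax(diag_logits, axis=1)
    delin_pred = np.argmax(delin_logits, axis=1)

    sel_delin = np.flatnonzero(
        (contrastive_labels == MALIGNANT) & (diag_pred == DIAG_MALIGNANT))
    sel_diag = np.flatnonzero(
        (contrastive_labels == HEALTHY) & (delin_pred == DELIN_HEALTHY))

    grad_diag = np.zeros_like(np.asarray(diag_logits, dtype=np.float64))
    grad_delin = np.zeros_like(grad_diag)
    n_contrib = len(sel_delin) + len(sel_diag)
    if n_contrib == 0:
        return 0.0, grad_diag, grad_delin

    total = 0.0
    if len(sel_delin):
        loss, g = cross_entropy(np.asarray(delin_logits)[sel_delin],
                                np.full(len(sel_delin), DELIN_LESION))
        total += loss * len(sel_delin)
        grad_delin[sel_delin] = g * len(sel_delin) / n_contrib
    if len(sel_diag):
        loss, g = cross_entropy(np.asarray(diag_logits)[sel_diag],
                                np.full(len(sel_diag), DIAG_BENIGN_SIDE))
        total += loss * len(sel_diag)
        grad_diag[sel_diag] = g * len(sel_diag) / n_contrib
    return total / n_contrib, grad_diag, grad_delin


def consistency_loss(diag_logits, delin_logits, contrastive_labels) -> float:
    loss, _, _ = consistency_loss_and_grad(diag_logits, delin_logits,
                                           contrastive_labels)
    return loss


@dataclass
class MultitaskLossReport:
    ce_diag: float
    ce_delin: float
    l_reg: float
    l_mt: float


def multitask_loss(diag_logits: np.ndarray, delin_logits: np.ndarray,
                   diag_labels: np.ndarray, delin_labels: np.ndarray,
                   contrastive_labels: np.ndarray,
                   diag_weights: np.ndarray | None = None,
                   delin_weights: np.ndarray | None = None,
                   use_consistency: bool = True):
    """L_MT = CE_diag + CE_delin + L_reg, with gradients for both heads.

    Returns ``(MultitaskLossReport, grad_diag, grad_delin)``.
    """
    ce_diag, g_diag = cross_entropy(diag_logits, diag_labels, diag_weights)
    ce_delin, g_delin = cross_entropy(delin_logits, delin_labels, delin_weights)
    if use_consistency:
        l_reg, gr_diag, gr_delin = consistency_loss_and_grad(
            diag_logits, delin_logits, contrastive_labels)
        g_diag = g_diag + gr_diag
        g_delin = g_delin + gr_delin
    else:
        l_reg = 0.0
    report = MultitaskLossReport(ce_diag=ce_diag, ce_delin=ce_delin,
                                 l_reg=l_reg, l_mt=ce_diag + ce_delin + l_reg)
    return report, g_diag, g_delin
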