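"""Preprocessing: raw maFLIM images to 900-dimensional network inputs.

The chain mirrors the acquisition-to-network pipeline: spatial median
filtering (SNR improvement, image size preserved), SNR-based pixel
masking, then per pixel — signal inversion (raw decays are
negative-going), zero-padding of each channel to a fixed length (default
300 samples, giving 3 x 300 = 900 inputs), per-channel calibration, and
normalization of the concatenated vector to sum to 100 (gain invariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (MALIGNANT_DIAGNOSES, DIAG_BENIGN, DIAG_NONE,
                   TISSUE_HEALTHY, TISSUE_LESION, DecayPixel, MaflimImage)
from .losses import (BENIGN, DELIN_HEALTHY, DELIN_LESION, DIAG_BENIGN_SIDE,
                     DIAG_MALIGNANT, HEALTHY, MALIGNANT)

#: Default padded per-channel length: 3 channels x 300 samples = 900 inputs.
PAD_LENGTH = 300

#: Cap applied to the SNR statistic where the tail noise estimate is ~0.
SNR_CAP = 1e6


class DegeneratePixelError(ValueError):
    """A pixel that cannot be sum-normalized (non-positive total signal)."""


class DegenerateImageError(ValueError):
    """An image with no unmasked pixels where at least one is required."""


class MetadataError(ValueError):
    """Image metadata inconsistent with the requested labeling."""


# ---------------------------------------------------------------------------
# image-level steps
# ---------------------------------------------------------------------------

def _median2d_clipped(plane: np.ndarray, window: int) -> np.ndarray:
    """Median over a window clipped at the image borders (size preserved)."""
    h, w = plane.shape
    r = window // 2
    padded = np.full((h + 2 * r, w + 2 * r), np.nan)
    padded[r:r + h, r:r + w] = plane
    stack = np.empty((window * window, h, w))
    k = 0
    for i in range(window):
        for j in range(window):
            stack[k] = padded[i:i + h, j:j + w]
            k += 1
    return np.nanmedian(stack, axis=0)


def median_filter(image: MaflimImage, window: int = 3) -> MaflimImage:
    """Sliding-window spatial median, applied per (channel, time) slice.

    The window is clipped at the borders, so the image plane keeps its
    original size. ``window`` must be odd; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"median filter window must be odd and >= 1, got {window}")
    if window == 1:
        filtered = image.tensor.copy()
    else:
        h, w, n_ch, n_t = image.tensor.shape
        filtered = np.empty_like(image.tensor)
        for c in range(n_ch):
            for t in range(n_t):
                filtered[:, :, c, t] = _median2d_clipped(image.tensor[:, :, c, t],
                                                         window)
    return MaflimImage(tensor=filtered, patient_id=image.patient_id,
                       tissue_type=image.tissue_type, diagnosis=image.diagnosis,
                       calibration=image.calibration.copy(),
                       snr_mask=None if image.snr_mask is None
                       else image.snr_mask.copy(),
                       time_step=image.time_step)


def compute_snr_mask(image: MaflimImage, threshold: float,
                     tail_fraction: float = 0.1,
                     snr_cap: float = SNR_CAP) -> np.ndarray:
    """Boolean keep-mask from a per-pixel SNR statistic.

    SNR = (peak absolute amplitude over all channels) / (standard
    deviation of the final ``tail_fraction`` of samples of the weakest
    channel), with the denominator floored at machine epsilon and the
    ratio capped at ``snr_cap``. A pixel is kept where SNR >= threshold.
    """
    if threshold < 0:
        raise ValueError("SNR threshold must be non-negative")
    a = np.abs(image.tensor)                      # (H, W, C, T)
    n_t = a.shape[3]
    peak = a.max(axis=(2, 3))
    ch_peak = a.max(axis=3)                       # (H, W, C)
    weakest = np.argmin(ch_peak, axis=2)          # (H, W)
    n_tail = max(1, int(np.ceil(tail_fraction * n_t)))
    tails = np.take_along_axis(
        a[:, :, :, n_t - n_tail:], weakest[:, :, None, None], axis=2
    )[:, :, 0, :]                                 # (H, W, n_tail)
    noise_sd = np.maximum(tails.std(axis=2), np.finfo(float).eps)
    snr = np.minimum(peak / noise_sd, snr_cap)
    return snr >= threshold


# ---------------------------------------------------------------------------
# pixel-level steps
# ---------------------------------------------------------------------------

def preprocess_pixel(raw: DecayPixel, calibration, per_channel_length: int = PAD_LENGTH,
                     ) -> DecayPixel:
    """Inversion -> zero-pad -> calibrate -> concatenate -> sum-to-100.

    Steps are applied in that fixed order. Zero padding is appended at the
    end of each channel (decay onset stays aligned at t = 0). A pixel whose
    calibrated total signal is not positive cannot be normalized and
    raises :class:`DegeneratePixelError`.
    """
    if raw.stage != "raw":
        raise ValueError("preprocess_pixel expects a raw pixel")
    calibration = np.asarray(calibration, dtype=np.float64)
    if calibration.shape != (raw.n_channels,) or np.any(calibration <= 0):
        raise ValueError("calibration must be one positive factor per channel")
    if per_channel_length < raw.channel_length:
        raise ValueError("per_channel_length shorter than the raw channel")

    out = np.zeros(raw.n_channels * per_channel_length)
    for k in range(raw.n_channels):
        seg = -raw.channel(k)                        # (1) inversion
        start = k * per_channel_length
        out[start:start + raw.channel_length] = seg  # (2) pad at channel end
        out[start:start + per_channel_length] *= calibration[k]  # (3)
    total = out.sum()                                # (4) concatenated above
    if total <= 0:
        raise DegeneratePixelError(
            f"pixel total signal {total} cannot be normalized to 100")
    out *= 100.0 / total                             # (5) sum-to-100
    return DecayPixel(values=out, channel_length=per_channel_length,
                      n_channels=raw.n_channels, stage="preprocessed")


def preprocess_image_pixels(image: MaflimImage,
                            per_channel_length: int = PAD_LENGTH) -> np.ndarray:
    """Vectorized pixel preprocessing over an image's unmasked pixels.

    Returns an (n_unmasked, n_channels * per_channel_length) matrix in
    row-major (row, column) pixel order.
    """
    h, w, n_ch, n_t = image.tensor.shape
    if per_channel_length < n_t:
        raise ValueError("per_channel_length shorter than the raw channel")
    mask = image.mask
    raw = image.tensor[mask]                         # (n, C, T)
    inverted = -raw
    padded = np.zeros((inverted.shape[0], n_ch, per_channel_length))
    padded[:, :, :n_t] = inverted
    padded *= image.calibration[None, :, None]
    flat = padded.reshape(inverted.shape[0], -1)
    totals = flat.sum(axis=1)
    if np.any(totals <= 0):
        raise DegeneratePixelError(
            f"{int(np.sum(totals <= 0))} unmasked pixels have non-positive "
            "total signal; mask them before preprocessing")
    return flat * (100.0 / totals[:, None])


# ---------------------------------------------------------------------------
# labels and training-pixel extraction
# ---------------------------------------------------------------------------

def map_labels(tissue_type: str, diagnosis: str) -> tuple[int, int, int]:
    """(contrastive, delineation, diagnosis) labels from image metadata.

    Contrastive: healthy / benign / malignant, with dysplasia and SCC both
    grouped as malignant. Delineation: lesion vs healthy (benign and
    malignant lesions share the lesion class). Diagnosis: malignant vs
    benign-side (healthy grouped with benign).
    """
    if tissue_type == TISSUE_HEALTHY:
        return HEALTHY, DELIN_HEALTHY, DIAG_BENIGN_SIDE
    if tissue_type == TISSUE_LESION:
        if diagnosis in MALIGNANT_DIAGNOSES:
            return MALIGNANT, DELIN_LESION, DIAG_MALIGNANT
        if diagnosis == DIAG_BENIGN:
            return BENIGN, DELIN_LESION, DIAG_BENIGN_SIDE
        raise MetadataError(
            f"lesion image requires a diagnosis, got {diagnosis!r}")
    raise MetadataError(f"unknown tissue type {tissue_type!r}")


@dataclass
class PixelDataset:
    """Aligned arrays of preprocessed pixels and their task labels."""

    X: np.ndarray             # (n, d) preprocessed pixel vectors
    contrastive: np.ndarray   # (n,) 3-class labels
    delineation: np.ndarray   # (n,) lesion vs healthy
    diagnosis: np.ndarray     # (n,) malignant vs benign-side
    patient_id: np.ndarray    # (n,)

    def __post_init__(self):
        n = len(self.X)
        for arr in (self.contrastive, self.delineation, self.diagnosis,
                    self.patient_id):
            if len(arr) != n:
                raise ValueError("misaligned PixelDataset arrays")

    def __len__(self) -> int:
        return len(self.X)

    def records(self) -> list[tuple[np.ndarray, dict[str, int], int]]:
        """Per-pixel (vector, labels, patient id) tuples."""
        return [
            (self.X[i],
             {"contrastive": int(self.contrastive[i]),
              "delineation": int(self.delineation[i]),
              "diagnosis": int(self.diagnosis[i])},
             int(self.patient_id[i]))
            for i in range(len(self))
        ]

    def subset(self, idx) -> "PixelDataset":
        return PixelDataset(self.X[idx], self.contrastive[idx],
                            self.delineation[idx], self.diagnosis[idx],
                            self.patient_id[idx])

    @classmethod
    def concat(cls, parts: list["PixelDataset"]) -> "PixelDataset":
        if not parts:
            raise ValueError("cannot concatenate an empty list of datasets")
        return cls(*[np.concatenate([getattr(p, f) for p in parts])
                     for f in ("X", "contrastive", "delineation",
                               "diagnosis", "patient_id")])


def image_to_training_pixels(image: MaflimImage,
                             per_channel_length: int = PAD_LENGTH) -> PixelDataset:
    """One training record per unmasked pixel of a preprocessed image."""
    contr, delin, diag = map_labels(image.tissue_type, image.diagnosis)
    n = int(image.mask.sum())
    if n == 0:
        d = image.tensor.shape[2] * per_channel_length
        empty = np.empty(0, dtype=np.int64)
        return PixelDataset(np.empty((0, d)), empty, empty, empty, empty)
    X = preprocess_image_pixels(image, per_channel_length)
    full = np.full(n, 0, dtype=np.int64)
    return PixelDataset(
        X=X,
        contrastive=full + contr,
        delineation=np.full(n, delin, dtype=np.int64),
        diagnosis=np.full(n, diag, dtype=np.int64),
        patient_id=np.full(n, image.patient_id, dtype=np.int64),
    )
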