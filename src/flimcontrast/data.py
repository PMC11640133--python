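"""Core data containers: decay pixels, maFLIM images, patient samples."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TISSUE_LESION = "lesion"
TISSUE_HEALTHY = "healthy"
DIAG_BENIGN = "benign"
DIAG_DYSPLASIA = "dysplasia"
DIAG_SCC = "SCC"
DIAG_NONE = "none"

#: Diagnoses grouped as malignant for all classification tasks
#: (dysplasia and squamous cell carcinoma form one malignant group).
MALIGNANT_DIAGNOSES = frozenset({DIAG_DYSPLASIA, DIAG_SCC})


@dataclass
class DecayPixel:
    """One pixel's multichannel fluorescence decay.

    ``values`` is the concatenation of the channel segments, each of length
    ``channel_length``. Raw pixels hold negative-going acquisition-style
    decays; preprocessed pixels are inverted, zero-padded, calibrated and
    sum-to-100 normalized.
    """

    values: np.ndarray
    channel_length: int
    n_channels: int = 3
    stage: str = "raw"  # "raw" | "preprocessed"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("pixel values must be a flat vector")
        if len(self.values) != self.n_channels * self.channel_length:
            raise ValueError(
                f"expected {self.n_channels}x{self.channel_length} samples, "
                f"got {len(self.values)}")

    def channel(self, k: int) -> np.ndarray:
        L = self.channel_length
        return self.values[k * L:(k + 1) * L]


@dataclass
class MaflimImage:
    """A maFLIM image: (H, W, channels, time) decay tensor plus metadata."""

    tensor: np.ndarray
    patient_id: int
    tissue_type: str                     # lesion | healthy
    diagnosis: str = DIAG_NONE           # benign | dysplasia | SCC | none
    calibration: np.ndarray = field(default_factory=lambda: np.ones(3))
    snr_mask: np.ndarray | None = None   # (H, W) booleans, True = keep
    time_step: float = 0.25              # ns

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 4:
            raise ValueError("image tensor must be (H, W, channels, time)")
        self.calibration = np.asarray(self.calibration, dtype=np.float64)
        if np.any(self.calibration <= 0):
            raise ValueError("calibration factors must be positive")
        if self.snr_mask is not None:
            self.snr_mask = np.asarray(self.snr_mask, dtype=bool)
            if self.snr_mask.shape != self.tensor.shape[:2]:
                raise ValueError("snr mask must match the image plane")
        if self.tissue_type not in (TISSUE_LESION, TISSUE_HEALTHY):
            raise ValueError(f"unknown tissue type {self.tissue_type!r}")

    @property
    def shape(self):
        return self.tensor.shape

    @property
    def mask(self) -> np.ndarray:
        if self.snr_mask is None:
            return np.ones(self.tensor.shape[:2], dtype=bool)
        return self.snr_mask


@dataclass
class PatientSample:
    """A patient's paired acquisition: one lesion and one healthy image."""

    patient_id: int
    diagnosis: str
    lesion: MaflimImage
    healthy: MaflimImage

    def __post_init__(self):
        if self.lesion.tissue_type != TISSUE_LESION:
            raise ValueError("lesion slot must hold a lesion image")
        if self.healthy.tissue_type != TISSUE_HEALTHY:
            raise ValueError("healthy slot must hold a healthy image")

    @property
    def images(self) -> list[MaflimImage]:
        return [self.lesion, self.healthy]
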