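"""Synthetic data generators.

Two families of synthetic data stand in for the private clinical dataset:

* **Interleaved 2-D arcs** (``make_arcs``): two- or three-class "moons"
  point clouds used to validate the contrastive loss machinery on data
  whose difficulty we control. Points carry synthetic patient ids so the
  patient-mean anchor machinery is exercisable in 2-D.

* **maFLIM cohorts** (``simulate_cohort``): per-patient pairs of lesion
  and healthy images whose pixels hold three biexponential-like channel
  decays at 0.25 ns resolution, with class-dependent lifetime shifts,
  patient-level nuisance variability, and additive Gaussian noise. Raw
  decays are stored negative-going, matching the acquisition convention
  that the preprocessing inversion step undoes.

The decay parameter magnitudes are configuration knobs chosen to produce
the qualitative structure the method must overcome (malignant lesions get
shorter NADH/FAD-channel lifetimes, consistent with the decreased redox
ratio of malignant tissue; patient effects perturb all lifetimes of a
patient's two images identically); they are not claims about real tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from sklearn.datasets import make_moons

from .data import (DIAG_BENIGN, DIAG_DYSPLASIA, DIAG_NONE, DIAG_SCC,
                   TISSUE_HEALTHY, TISSUE_LESION, DecayPixel, MaflimImage,
                   PatientSample)

# ---------------------------------------------------------------------------
# 2-D interleaved arcs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Labeled2DPoint:
    x: np.ndarray          # 2-vector
    class_label: int
    patient_id: int


def make_arcs(n_per_class: int, n_classes: int, noise_sd: float,
              seed: int, patients_per_class: int = 2) -> list[Labeled2DPoint]:
    """Interleaved-arc point clouds with 2 or 3 exactly balanced classes.

    The two-class case is the scikit-learn two-moons dataset. The third
    class is the upper arc of an independently sampled moons pair,
    translated to sit adjacent to the first two so the interleaved,
    nonlinearly separable geometry is preserved. Points are assigned
    synthetic patient ids in contiguous blocks within each class.
    """
    if n_classes not in (2, 3):
        raise ValueError(f"n_classes must be 2 or 3, got {n_classes}")
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")
    if n_per_class == 0:
        return []

    ss = np.random.SeedSequence(seed)
    states = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
    X, y = make_moons(n_samples=2 * n_per_class, noise=noise_sd,
                      random_state=states[0])
    clouds = [X[y == 0], X[y == 1]]
    if n_classes == 3:
        X2, y2 = make_moons(n_samples=2 * n_per_class, noise=noise_sd,
                            random_state=states[1])
        clouds.append(X2[y2 == 0] + np.array([2.0, 0.0]))

    points: list[Labeled2DPoint] = []
    block = max(1, int(np.ceil(n_per_class / patients_per_class)))
    for c, cloud in enumerate(clouds):
        for i, xy in enumerate(cloud):
            points.append(Labeled2DPoint(
                x=np.asarray(xy, dtype=np.float64),
                class_label=c,
                patient_id=c * patients_per_class + i // block,
            ))
    return points


def arcs_to_arrays(points: list[Labeled2DPoint]):
    """Stack a point list into (X, class_labels, patient_ids) arrays."""
    X = np.array([p.x for p in points]).reshape(len(points), -1)
    y = np.array([p.class_label for p in points], dtype=np.int64)
    pids = np.array([p.patient_id for p in points], dtype=np.int64)
    return X, y, pids


# ---------------------------------------------------------------------------
# fluorescence decay simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecayModelParams:
    """Biexponential decay model per channel.

    ``amplitudes`` and ``lifetimes`` are (n_channels, 2) arrays: photon
    amplitudes (arbitrary units, >= 0) and lifetimes tau1/tau2 (ns, > 0).
    Each channel's clean decay is
    ``gain * (A1 exp(-t/tau1) + A2 exp(-t/tau2))`` sampled at
    ``t_i = i * time_step`` for ``i = 0 .. n_samples-1``, with additive
    zero-mean Gaussian noise of standard deviation ``noise_scale``.
    """

    amplitudes: np.ndarray
    lifetimes: np.ndarray
    n_samples: int = 250
    time_step: float = 0.25     # ns
    noise_scale: float = 0.0
    gain: float = 1.0

    def __post_init__(self):
        amps = np.atleast_2d(np.asarray(self.amplitudes, dtype=np.float64))
        taus = np.atleast_2d(np.asarray(self.lifetimes, dtype=np.float64))
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "lifetimes", taus)
        if amps.shape != taus.shape or amps.shape[1] != 2:
            raise ValueError("amplitudes and lifetimes must be (n_channels, 2)")
        if np.any(taus <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        if self.time_step <= 0:
            raise ValueError("time step must be positive")
        if self.n_samples < 1:
            raise ValueError("need at least one time sample")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[0]

    def clean_decays(self) -> np.ndarray:
        """Noiseless positive-going decays, shape (n_channels, n_samples)."""
        t = np.arange(self.n_samples) * self.time_step
        a1, a2 = self.amplitudes[:, 0:1], self.amplitudes[:, 1:2]
        t1, t2 = self.lifetimes[:, 0:1], self.lifetimes[:, 1:2]
        return self.gain * (a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2))


def simulate_pixel_decay(params: DecayModelParams, seed: int) -> DecayPixel:
    """One raw pixel: noisy biexponential decays, stored negative-going."""
    rng = np.random.default_rng(seed)
    clean = params.clean_decays()
    noisy = clean + params.noise_scale * rng.standard_normal(clean.shape)
    return DecayPixel(values=-noisy.ravel(), channel_length=params.n_samples,
                      n_channels=params.n_channels, stage="raw")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: Baseline (healthy-tissue) biexponential parameters for the three
#: emission channels (collagen, NADH, FAD): amplitudes sum to ~1, lifetime
#: pairs in ns. Chosen as plausible tissue-autofluorescence magnitudes.
BASE_AMPLITUDES = np.array([[0.55, 0.45],
                            [0.60, 0.40],
                            [0.50, 0.50]])
BASE_LIFETIMES = np.array([[5.2, 1.4],
                           [4.0, 0.9],
                           [4.6, 1.2]])


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated patient cohort.

    Each patient contributes exactly two images: a lesion image (benign or
    malignant diagnosis) and a healthy-tissue image. ``class_effect``
    scales the relative lifetime shift distinguishing lesion classes;
    ``patient_effect`` is the sigma of a multiplicative lognormal
    perturbation of all of a patient's lifetimes (shared by both images),
    emulating inter-patient variability.
    """

    n_benign: int
    n_malignant: int
    image_size: tuple[int, int] = (160, 160)
    class_effect: float = 0.15
    patient_effect: float = 0.05
    noise_scale: float = 0.02
    channel_length: int = 250
    time_step: float = 0.25
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("patient counts must be non-negative")
        if self.n_benign + self.n_malignant == 0:
            raise ValueError("cohort must contain at least one patient")
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image size must be at least 1x1")
        if self.class_effect < 0 or self.patient_effect < 0 or self.noise_scale < 0:
            raise ValueError("effect magnitudes must be non-negative")

    @property
    def n_patients(self) -> int:
        return self.n_benign + self.n_malignant


def class_lifetimes(tissue_class: str, class_effect: float) -> np.ndarray:
    """Per-channel lifetime pairs for a tissue class.

    Healthy tissue uses the baseline; benign lesions get longer collagen-
    and NADH-channel lifetimes (structural remodeling signature); malignant
    lesions get shorter NADH/FAD-channel lifetimes (metabolic signature of
    a decreased redox ratio).
    """
    taus = BASE_LIFETIMES.copy()
    if tissue_class == "benign":
        taus[0] *= 1.0 + 0.6 * class_effect
        taus[1] *= 1.0 + 0.3 * class_effect
    elif tissue_class == "malignant":
        taus[1] *= 1.0 - class_effect
        taus[2] *= 1.0 - class_effect
    elif tissue_class != "healthy":
        raise ValueError(f"unknown tissue class {tissue_class!r}")
    return taus


def _simulate_image(taus: np.ndarray, spec: CohortSpec, patient_id: int,
                    tissue_type: str, diagnosis: str,
                    rng: np.random.Generator) -> MaflimImage:
    h, w = spec.image_size
    params = DecayModelParams(
        amplitudes=BASE_AMPLITUDES, lifetimes=taus,
        n_samples=spec.channel_length, time_step=spec.time_step,
        noise_scale=spec.noise_scale, gain=spec.gain)
    clean = params.clean_decays()                       # (3, L)
    tensor = np.broadcast_to(clean, (h, w, *clean.shape)).copy()
    if spec.noise_scale > 0:
        tensor += spec.noise_scale * rng.standard_normal(tensor.shape)
    return MaflimImage(tensor=-tensor, patient_id=patient_id,
                       tissue_type=tissue_type, diagnosis=diagnosis,
                       time_step=spec.time_step)


def iter_cohort(spec: CohortSpec) -> Iterator[PatientSample]:
    """Stream patients one at a time (full-scale cohorts are large)."""
    ss = np.random.SeedSequence(spec.seed)
    # benign patients first, then malignant; every 6th malignant patient is
    # dysplasia, the rest SCC, exercising the diagnosis-grouping rule
    roster = [(i, DIAG_BENIGN) for i in range(spec.n_benign)]
    roster += [(spec.n_benign + i,
                DIAG_DYSPLASIA if i % 6 == 5 else DIAG_SCC)
               for i in range(spec.n_malignant)]
    for (pid, diagnosis), child in zip(roster, ss.spawn(len(roster))):
        rng = np.random.default_rng(child)
        patient_factor = (np.exp(spec.patient_effect * rng.standard_normal())
                          if spec.patient_effect > 0 else 1.0)
        lesion_class = ("malignant" if diagnosis in (DIAG_DYSPLASIA, DIAG_SCC)
                        else "benign")
        lesion = _simulate_image(
            class_lifetimes(lesion_class, spec.class_effect) * patient_factor,
            spec, pid, TISSUE_LESION, diagnosis, rng)
        healthy = _simulate_image(
            class_lifetimes("healthy", spec.class_effect) * patient_factor,
            spec, pid, TISSUE_HEALTHY, DIAG_NONE, rng)
        yield PatientSample(patient_id=pid, diagnosis=diagnosis,
                            lesion=lesion, healthy=healthy)


def simulate_cohort(spec: CohortSpec) -> list[PatientSample]:
    """Materialize the whole cohort (see ``iter_cohort`` for streaming)."""
    return list(iter_cohort(spec))
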