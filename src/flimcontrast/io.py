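"""Cohort container I/O: one HDF5 file per cohort plus a CSV manifest.

Layout: datasets ``/patients/<id>/lesion`` and ``/patients/<id>/healthy``
of shape (H, W, 3, L) with per-image attributes (diagnosis, tissue type,
calibration factors, time step) and optional boolean ``*_mask`` datasets.
The manifest CSV (same stem, ``.csv``) mirrors the container with one row
per image: patient_id, tissue_type, diagnosis, path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .data import MaflimImage, PatientSample


def write_cohort(path, patients: Iterable[PatientSample],
                 seed: int | None = None, manifest: bool = True) -> Path:
    path = Path(path)
    rows = []
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = seed
        grp = f.create_group("patients")
        for patient in patients:
            pg = grp.create_group(str(patient.patient_id))
            for tissue, image in (("lesion", patient.lesion),
                                  ("healthy", patient.healthy)):
                ds = pg.create_dataset(tissue, data=image.tensor)
                ds.attrs["diagnosis"] = image.diagnosis
                ds.attrs["tissue_type"] = image.tissue_type
                ds.attrs["calibration"] = image.calibration
                ds.attrs["time_step"] = image.time_step
                if image.snr_mask is not None:
                    pg.create_dataset(f"{tissue}_mask", data=image.snr_mask)
                rows.append({"patient_id": patient.patient_id,
                             "tissue_type": tissue,
                             "diagnosis": image.diagnosis,
                             "path": f"/patients/{patient.patient_id}/{tissue}"})
    if manifest:
        pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
    return path


def _read_image(pg: h5py.Group, tissue: str, patient_id: int) -> MaflimImage:
    ds = pg[tissue]
    mask = pg[f"{tissue}_mask"][...] if f"{tissue}_mask" in pg else None
    return MaflimImage(tensor=ds[...], patient_id=patient_id,
                       tissue_type=str(ds.attrs["tissue_type"]),
                       diagnosis=str(ds.attrs["diagnosis"]),
                       calibration=np.asarray(ds.attrs["calibration"]),
                       snr_mask=mask,
                       time_step=float(ds.attrs["time_step"]))


def read_cohort(path) -> list[PatientSample]:
    patients = []
    with h5py.File(path, "r") as f:
        for pid_str in sorted(f["patients"], key=int):
            pid = int(pid_str)
            pg = f["patients"][pid_str]
            lesion = _read_image(pg, "lesion", pid)
            healthy = _read_image(pg, "healthy", pid)
            patients.append(PatientSample(patient_id=pid,
                                          diagnosis=lesion.diagnosis,
                                          lesion=lesion, healthy=healthy))
    return patients
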