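"""NIfTI and CSV I/O.

Images travel as NIfTI-1 with a diagonal affine built from (spacing, origin);
tables travel as CSV with fixed, documented column names:

* cohort table — subject_id, sex, height_cm, weight_kg, bmi,
  injected_dose_mbq, wait_time_min, half_life_min, tracer, water_mass_kg,
  fat_mass_kg, lung_mass_kg, residual_mass_kg
* DXA table — subject_id, fat_mass_kg, nonfat_mass_kg, coverage
* volumes table — subject_id, water_volume_l, fat_volume_l, lung_volume_l,
  air_volume_l
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    ActivityImage,
    AttenuationMap,
    BodyComposition,
    CompartmentLabelMap,
    CompartmentVolumes,
    DensityCalibration,
    DXARecord,
    SubjectRecord,
)

COHORT_COLUMNS = [
    "subject_id", "sex", "height_cm", "weight_kg", "bmi",
    "injected_dose_mbq", "wait_time_min", "half_life_min", "tracer",
    "water_mass_kg", "fat_mass_kg", "lung_mass_kg", "residual_mass_kg",
]
DXA_COLUMNS = ["subject_id", "fat_mass_kg", "nonfat_mass_kg", "coverage"]
VOLUME_COLUMNS = [
    "subject_id", "water_volume_l", "fat_volume_l", "lung_volume_l", "air_volume_l",
]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti(image: AttenuationMap | CompartmentLabelMap | ActivityImage, path) -> None:
    grid = image.grid
    if grid.dtype == np.int8:
        grid = grid.astype(np.uint8)
    nib.save(nib.Nifti1Image(grid, _affine(image.spacing, image.origin)), str(path))


def _load_grid(path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return np.asarray(img.dataobj), spacing, origin


def load_attenuation(path) -> AttenuationMap:
    grid, spacing, origin = _load_grid(path)
    return AttenuationMap(grid.astype(np.float64), spacing, origin)


def load_labels(path) -> CompartmentLabelMap:
    grid, spacing, origin = _load_grid(path)
    return CompartmentLabelMap(grid.astype(np.int8), spacing, origin)


def load_activity(path) -> ActivityImage:
    grid, spacing, origin = _load_grid(path)
    return ActivityImage(grid.astype(np.float64), spacing, origin)


def cohort_to_frame(cohort: list[tuple[SubjectRecord, BodyComposition]]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "sex": s.sex,
            "height_cm": s.height,
            "weight_kg": s.weight,
            "bmi": s.bmi,
            "injected_dose_mbq": s.injected_dose,
            "wait_time_min": s.wait_time,
            "half_life_min": s.half_life,
            "tracer": s.tracer,
            "water_mass_kg": c.water_mass,
            "fat_mass_kg": c.fat_mass,
            "lung_mass_kg": c.lung_mass,
            "residual_mass_kg": c.residual_mass,
        }
        for s, c in cohort
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[tuple[SubjectRecord, BodyComposition]]:
    cohort = []
    for row in df.itertuples(index=False):
        subject = SubjectRecord(
            subject_id=row.subject_id,
            sex=row.sex,
            height=row.height_cm,
            weight=row.weight_kg,
            injected_dose=row.injected_dose_mbq,
            wait_time=row.wait_time_min,
            half_life=row.half_life_min,
            tracer=row.tracer,
        )
        comp = BodyComposition(
            row.water_mass_kg, row.fat_mass_kg, row.lung_mass_kg, row.residual_mass_kg
        )
        cohort.append((subject, comp))
    return cohort


def dxa_to_frame(records: list[DXARecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "fat_mass_kg": r.fat_mass,
            "nonfat_mass_kg": r.nonfat_mass,
            "coverage": r.coverage,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=DXA_COLUMNS)


def frame_to_dxa(df: pd.DataFrame) -> list[DXARecord]:
    return [
        DXARecord(r.subject_id, r.fat_mass_kg, r.nonfat_mass_kg, r.coverage)
        for r in df.itertuples(index=False)
    ]


def volumes_to_frame(volumes: list[tuple[str, CompartmentVolumes]]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": sid,
            "water_volume_l": v.water_volume,
            "fat_volume_l": v.fat_volume,
            "lung_volume_l": v.lung_volume,
            "air_volume_l": v.air_volume,
        }
        for sid, v in volumes
    ]
    return pd.DataFrame(rows, columns=VOLUME_COLUMNS)


def frame_to_volumes(df: pd.DataFrame) -> list[tuple[str, CompartmentVolumes]]:
    return [
        (
            r.subject_id,
            CompartmentVolumes(
                r.water_volume_l, r.fat_volume_l, r.lung_volume_l, r.air_volume_l
            ),
        )
        for r in df.itertuples(index=False)
    ]


def save_calibration(cal: DensityCalibration, path) -> None:
    Path(path).write_text(json.dumps(asdict(cal), indent=2, sort_keys=True) + "\n")


def load_calibration(path) -> DensityCalibration:
    return DensityCalibration(**json.loads(Path(path).read_text()))
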