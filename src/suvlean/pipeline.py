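"""End-to-end synthetic study orchestration.

``run_study`` wires the full chain: sample a cohort -> build voxel phantoms
-> simulate DXA and PET -> segment the attenuation maps and compute
compartment volumes -> calibrate tissue densities on the DXA sub-cohort ->
estimate LBM by every method -> quantify organ SUVs -> emit the agreement
and BMI-dependence tables. Deterministic given the config seed; every output
directory carries a manifest with the seed and a config hash.

The default configuration mimics an FDG-arm study: 90 subjects, of whom the
first 40 receive a same-day DXA scan used for density calibration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .errors import EmptyROIError, PipelineError
from .lbm import dxa_lean_fraction, lbm_estimate
from .mrac import compartment_volumes, dixon_lean_fraction, fit_density_multi, segment_mrac
from .stats import bmi_subgroup_table, build_suv_bmi_table, lbm_agreement_table
from .suv import apply_lbm_correction, roi_statistics, sphere_roi, suv_bw, threshold_roi
from .synthetic import (
    build_phantom,
    default_fdg_profile,
    default_grid,
    default_psma_profile,
    generate_cohort,
    simulate_dxa,
    simulate_pet,
)
from .types import DensityCalibration, GridSpec, LBMEstimate

logger = logging.getLogger("suvlean")

_PKG_VERSION = "0.1.0"


@dataclass
class StudyConfig:
    """Frozen description of one synthetic study run."""

    n: int = 90
    dxa_n: int = 40
    seed: int = 7
    spacing_mm: float = 8.0
    tracer: str = "FDG"
    dxa_noise_cv: float = 0.02
    pet_noise_sd: float = 0.3  # kBq/mL, voxelwise
    organ_cv: float = 0.15  # per-organ biological variability (lognormal CV)
    brain_threshold: float = 2.5  # SUV threshold for the brain ROI
    liver_roi_diameter: float = 30.0  # mm
    blood_roi_diameter: float = 10.0  # mm
    uptake_overrides: dict = field(default_factory=dict)
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        # out_dir is run plumbing, not part of the study definition: two runs
        # of the same study into different directories share a config hash.
        d = asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class StudyResult:
    config: StudyConfig
    cohort: pd.DataFrame
    dxa: pd.DataFrame
    volumes: pd.DataFrame
    calibration: DensityCalibration
    lbm: pd.DataFrame
    measurements: pd.DataFrame
    lbm_agreement: pd.DataFrame
    suv_bmi: pd.DataFrame
    subgroups: pd.DataFrame


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise any failure naming the stage."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def _nearest_voxel_roi(grid: GridSpec, center) -> np.ndarray:
    ijk = [
        int(np.clip(round((center[a] - grid.origin[a]) / grid.spacing[a]), 0, grid.shape[a] - 1))
        for a in range(3)
    ]
    return np.array([np.ravel_multi_index(ijk, grid.shape)])


def _sphere_or_nearest(grid: GridSpec, center, diameter: float) -> np.ndarray:
    """Sphere ROI, degrading to the single nearest voxel when the sphere is
    smaller than the voxel lattice can resolve."""
    try:
        return sphere_roi(grid, center, diameter)
    except EmptyROIError:
        return _nearest_voxel_roi(grid, center)


def run_study(config: StudyConfig) -> StudyResult:
    """Run the synthetic study; write outputs if ``config.out_dir`` is set."""
    base = np.random.SeedSequence(config.seed)
    # independent, reproducible substreams per stochastic stage
    seed_cohort, seed_dxa, seed_pet = (
        int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(3)
    )

    with _stage("cohort"):
        profile = default_psma_profile() if config.tracer == "PSMA" else default_fdg_profile()
        cohort = generate_cohort(config.n, seed_cohort, profile)
        cohort_df = sio.cohort_to_frame(cohort)

    grid = default_grid(config.spacing_mm)
    dxa_ids = [s.subject_id for s, _ in cohort[: config.dxa_n]]

    with _stage("dxa"):
        dxa_rng = np.random.default_rng(seed_dxa)
        dxa_records = [
            simulate_dxa(
                comp,
                noise_cv=config.dxa_noise_cv,
                seed=int(dxa_rng.integers(2**31)),
                subject_id=subj.subject_id,
            )
            for subj, comp in cohort[: config.dxa_n]
        ]
        dxa_df = sio.dxa_to_frame(dxa_records)

    with _stage("volumetrics"):
        volumes = []
        labels_by_id = {}
        for subj, comp in cohort:
            attn, _ = build_phantom(comp, grid)
            labels = segment_mrac(attn)
            labels_by_id[subj.subject_id] = labels
            volumes.append((subj.subject_id, compartment_volumes(labels)))
        volumes_df = sio.volumes_to_frame(volumes)

    with _stage("calibration"):
        vol_by_id = dict(volumes)
        pairs = [(vol_by_id[r.subject_id], r) for r in dxa_records]
        if len(pairs) >= 4:
            calibration = fit_density_multi(pairs)
        else:
            logger.warning("DXA sub-cohort too small to calibrate; using nominal densities")
            calibration = DensityCalibration.nominal()

    with _stage("lbm"):
        lbm_rows = []
        dxa_by_id = {r.subject_id: r for r in dxa_records}
        estimates: dict[str, dict[str, LBMEstimate]] = {}
        fractions: dict[str, float] = {}
        for subj, comp in cohort:
            vols = vol_by_id[subj.subject_id]
            # The covered-mass lean fraction rescales SUVbw to SUV_dixon;
            # the Dixon lean *mass* is the calibrated water mass, so its
            # weight fraction is comparable with the DXA nonfat/weight%.
            frac = dixon_lean_fraction(vols, calibration)
            fractions[subj.subject_id] = frac
            dixon_mass = calibration.density_water * vols.water_volume
            per = {m: lbm_estimate(m, subj) for m in ("james", "janma")}
            per["dixon"] = LBMEstimate("dixon", dixon_mass, 100.0 * dixon_mass / subj.weight)
            estimates[subj.subject_id] = per
            row = {
                "subject_id": subj.subject_id,
                "sex": subj.sex,
                "bmi": subj.bmi,
                "frac_dixon": per["dixon"].fraction,
                "frac_james": per["james"].fraction,
                "frac_janma": per["janma"].fraction,
            }
            if subj.subject_id in dxa_by_id:
                row["frac_dxa"] = dxa_lean_fraction(dxa_by_id[subj.subject_id], subj.weight)
            lbm_rows.append(row)
        lbm_df = pd.DataFrame(lbm_rows)

    with _stage("suv"):
        pet_rng = np.random.default_rng(seed_pet)
        if config.uptake_overrides:
            uptake = dict(config.uptake_overrides)
        elif config.tracer == "PSMA":
            from .synthetic import DEFAULT_UPTAKE_PSMA

            uptake = dict(DEFAULT_UPTAKE_PSMA)
        else:
            uptake = None
        meas_rows = []
        for subj, comp in cohort:
            pet = simulate_pet(
                labels_by_id[subj.subject_id],
                subj,
                comp,
                uptake_profile=uptake,
                noise_sd=config.pet_noise_sd,
                seed=int(pet_rng.integers(2**31)),
                organ_cv=config.organ_cv,
            )
            suv_img = suv_bw(
                pet.grid, subj.injected_dose, subj.wait_time, subj.half_life, subj.weight
            )
            rois: dict[str, np.ndarray] = {}
            if "liver" in pet.organ_centers:
                rois["liver"] = _sphere_or_nearest(
                    grid, pet.organ_centers["liver"], config.liver_roi_diameter
                )
            if "blood" in pet.organ_centers:
                rois["blood"] = _sphere_or_nearest(
                    grid, pet.organ_centers["blood"], config.blood_roi_diameter
                )
            if "brain" in pet.organ_truth:
                idx = threshold_roi(suv_img, config.brain_threshold)
                if idx.size:
                    rois["brain"] = idx
            if "muscle" in pet.organ_truth:
                rois["muscle"] = pet.organ_truth["muscle"]
            for organ, roi in rois.items():
                mx, mn = roi_statistics(suv_img, roi)
                for statistic, value in (("max", mx), ("mean", mn)):
                    m = apply_lbm_correction(
                        value,
                        estimates[subj.subject_id],
                        subj.weight,
                        fractions[subj.subject_id],
                        organ=organ,
                        statistic=statistic,
                    )
                    meas_rows.append(
                        {
                            "subject_id": subj.subject_id,
                            "organ": organ,
                            "statistic": statistic,
                            "suv_bw": m.suv_bw,
                            "suv_dixon": m.suv_dixon,
                            "suv_james": m.suv_james,
                            "suv_janma": m.suv_janma,
                        }
                    )
        meas_df = pd.DataFrame(
            meas_rows,
            columns=[
                "subject_id", "organ", "statistic",
                "suv_bw", "suv_dixon", "suv_james", "suv_janma",
            ],
        )

    with _stage("report"):
        subjects_df = cohort_df.rename(columns={"bmi": "bmi"})[["subject_id", "bmi"]]
        dxa_lbm = lbm_df[lbm_df.subject_id.isin(dxa_ids)] if len(lbm_df) else lbm_df
        agreement = (
            lbm_agreement_table(dxa_lbm.dropna(subset=["frac_dxa"]))
            if len(dxa_lbm) and "frac_dxa" in dxa_lbm
            else pd.DataFrame()
        )
        suv_bmi = (
            build_suv_bmi_table(meas_df, subjects_df) if len(meas_df) else pd.DataFrame()
        )
        subgroups = (
            bmi_subgroup_table(meas_df, subjects_df) if len(meas_df) else pd.DataFrame()
        )

    result = StudyResult(
        config=config,
        cohort=cohort_df,
        dxa=dxa_df,
        volumes=volumes_df,
        calibration=calibration,
        lbm=lbm_df,
        measurements=meas_df,
        lbm_agreement=agreement,
        suv_bmi=suv_bmi,
        subgroups=subgroups,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: StudyResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(out / "cohort.csv", index=False)
    result.dxa.to_csv(out / "dxa.csv", index=False)
    result.volumes.to_csv(out / "volumes.csv", index=False)
    result.lbm.to_csv(out / "lbm.csv", index=False)
    result.measurements.to_csv(out / "suv_measurements.csv", index=False)
    result.lbm_agreement.to_csv(out / "lbm_agreement.csv", index=False)
    result.suv_bmi.to_csv(out / "suv_bmi_table.csv", index=False)
    result.subgroups.to_csv(out / "bmi_subgroups.csv", index=False)
    sio.save_calibration(result.calibration, out / "calibration.json")
    manifest = {
        "package": "suvlean",
        "version": _PKG_VERSION,
        "seed": result.config.seed,
        "config": result.config.to_dict(),
        "config_sha256": result.config.config_hash(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
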