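"""Synthetic cohort, voxel phantoms, DXA measurements and PET activity maps.

Everything downstream of this module (segmentation, density calibration,
LBM estimation, SUV quantitation, agreement statistics) is exercised on data
from these generators, so their defaults encode the study conditions:

* Demographics follow the FDG-arm cohort moments (weight 63 +/- 14.4 kg
  within 37-103, BMI ~23.1, height 165 +/- 7 cm within 150-183, dose
  221 +/- 50 MBq, uptake time 72 +/- 14 min, 48F/42M sex ratio), realised as
  per-sex truncated normals whose *truncated* means match the profile means.
* Body composition links fat fraction affinely to BMI with sex-specific
  intercepts (heavier-per-height subjects carry proportionally more fat), so
  the SUVbw-vs-BMI dependence the analysis targets is present by
  construction. 8% of body mass sits outside head-to-thigh coverage.
* Phantoms are quasi-ellipsoidal water bodies with a subcutaneous fat shell
  and two lung regions in an air background, with per-compartment voxel
  counts matching composition masses to within half a voxel-mass at the
  nominal densities (fat 0.79, water 1.23, lung 0.20 kg/L).
* PET forward model: organ activity = level * dose * decay / lean reference
  mass (water+lung), fat uptake exactly zero before noise, so lean-normalized
  SUV of an organ recovers its level while SUVbw inherits the fat burden.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError
from .suv import decay_factor, sphere_roi
from .types import (
    ActivityImage,
    AttenuationMap,
    BodyComposition,
    CompartmentLabelMap,
    DXARecord,
    F18_HALF_LIFE_MIN,
    GridSpec,
    LABEL_CODES,
    MU_VALUES,
    NOMINAL_DENSITIES,
    SubjectRecord,
)

__all__ = [
    "SexProfile",
    "CohortProfile",
    "default_fdg_profile",
    "default_grid",
    "generate_cohort",
    "build_phantom",
    "simulate_dxa",
    "simulate_pet",
    "DEFAULT_UPTAKE_FDG",
    "DEFAULT_UPTAKE_PSMA",
]


# --------------------------------------------------------------------------
# cohort profile
# --------------------------------------------------------------------------


@dataclass
class SexProfile:
    """Per-sex sampling parameters: truncated-normal height (cm) and weight
    (kg), and the affine BMI -> fat-fraction link."""

    height_mean: float
    height_sd: float
    height_bounds: tuple[float, float]
    weight_mean: float
    weight_sd: float
    weight_bounds: tuple[float, float]
    fat_intercept: float  # fat fraction at BMI 0 (affine link)
    fat_slope: float  # fat-fraction increase per BMI unit


@dataclass
class CohortProfile:
    """Demographic parameter set for :func:`generate_cohort`.

    The default profile (see :func:`default_fdg_profile`) mixes female and
    male sub-profiles so the pooled moments match the FDG-arm cohort.
    """

    female: SexProfile
    male: SexProfile
    female_fraction: float = 48.0 / 90.0
    dose_mean: float = 221.0  # MBq
    dose_sd: float = 50.0
    dose_bounds: tuple[float, float] = (20.0, 600.0)
    wait_mean: float = 72.0  # min
    wait_sd: float = 14.0
    wait_bounds: tuple[float, float] = (30.0, 150.0)
    tracer: str = "FDG"
    half_life: float = F18_HALF_LIFE_MIN
    fat_bounds: tuple[float, float] = (0.05, 0.55)
    lung_mass: float = 0.6  # kg, near-constant across adults
    residual_fraction: float = 0.08  # mass outside head-to-thigh coverage


def default_fdg_profile() -> CohortProfile:
    """FDG-arm demographic profile.

    Per-sex means are chosen so the 48F/42M mixture reproduces the pooled
    cohort moments (weight 63 kg, height 165 cm); within-sex SDs are the
    pooled SDs minus the between-sex variance component.
    """
    female = SexProfile(
        height_mean=160.5, height_sd=5.0, height_bounds=(150.0, 183.0),
        weight_mean=57.5, weight_sd=13.1, weight_bounds=(37.0, 103.0),
        fat_intercept=0.025, fat_slope=0.012,
    )
    male = SexProfile(
        height_mean=170.2, height_sd=5.0, height_bounds=(150.0, 183.0),
        weight_mean=69.3, weight_sd=13.1, weight_bounds=(37.0, 103.0),
        fat_intercept=-0.065, fat_slope=0.012,
    )
    return CohortProfile(female=female, male=male)


def default_psma_profile() -> CohortProfile:
    """PSMA-arm profile: all male, heavier/taller, ~2 h uptake time."""
    male = SexProfile(
        height_mean=170.0, height_sd=5.0, height_bounds=(162.0, 180.0),
        weight_mean=70.7, weight_sd=8.4, weight_bounds=(54.0, 87.0),
        fat_intercept=-0.065, fat_slope=0.012,
    )
    return CohortProfile(
        female=replace(male), male=male, female_fraction=0.0,
        dose_mean=314.0, dose_sd=73.0, wait_mean=141.0, wait_sd=18.0,
        tracer="PSMA",
    )


def _truncnorm_matching_mean(
    mean: float, sd: float, bounds: tuple[float, float]
) -> stats._distn_infrastructure.rv_frozen:
    """Frozen truncnorm on ``bounds`` whose truncated mean equals ``mean``.

    Truncation shifts the mean of a naively-parameterised truncated normal,
    so the underlying location is solved for (brentq) instead.
    """
    lo, hi = bounds
    if sd <= 0:
        raise ConfigurationError(f"sd must be > 0, got {sd}")
    if not lo < mean < hi:
        raise ConfigurationError(
            f"target mean {mean} outside truncation bounds ({lo}, {hi})"
        )

    def truncated_mean_gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    loc = optimize.brentq(truncated_mean_gap, lo - 10 * sd, hi + 10 * sd, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def generate_cohort(
    n: int,
    seed: int,
    profile: CohortProfile | None = None,
) -> list[tuple[SubjectRecord, BodyComposition]]:
    """Sample ``n`` subjects with ground-truth body composition.

    Deterministic given ``seed``. Heights and weights are per-sex truncated
    normals (independent within sex); BMI is derived; the fat fraction is an
    affine function of BMI truncated to ``profile.fat_bounds``; water mass is
    the remainder after fat, lung and residual (off-coverage) mass.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    profile = profile or default_fdg_profile()
    rng = np.random.default_rng(seed)

    samplers = {
        sex: (
            _truncnorm_matching_mean(p.height_mean, p.height_sd, p.height_bounds),
            _truncnorm_matching_mean(p.weight_mean, p.weight_sd, p.weight_bounds),
        )
        for sex, p in (("F", profile.female), ("M", profile.male))
    }
    dose_rv = _truncnorm_matching_mean(profile.dose_mean, profile.dose_sd, profile.dose_bounds)
    wait_rv = _truncnorm_matching_mean(profile.wait_mean, profile.wait_sd, profile.wait_bounds)

    cohort: list[tuple[SubjectRecord, BodyComposition]] = []
    for i in range(n):
        sex = "F" if rng.random() < profile.female_fraction else "M"
        sexp = profile.female if sex == "F" else profile.male
        height_rv, weight_rv = samplers[sex]
        height = float(height_rv.rvs(random_state=rng))
        weight = float(weight_rv.rvs(random_state=rng))
        bmi = weight / (height / 100.0) ** 2
        fat_frac = float(
            np.clip(sexp.fat_intercept + sexp.fat_slope * bmi, *profile.fat_bounds)
        )
        fat = fat_frac * weight
        residual = profile.residual_fraction * weight
        lung = profile.lung_mass
        water = weight - fat - residual - lung
        if water <= 0:
            raise ConfigurationError(
                f"profile yields non-positive water mass for subject {i} "
                f"(weight {weight:.1f} kg, fat fraction {fat_frac:.2f})"
            )
        subject = SubjectRecord(
            subject_id=f"S{i:04d}",
            sex=sex,
            height=height,
            weight=weight,
            injected_dose=float(dose_rv.rvs(random_state=rng)),
            wait_time=float(wait_rv.rvs(random_state=rng)),
            half_life=profile.half_life,
            tracer=profile.tracer,
        )
        cohort.append((subject, BodyComposition(water, fat, lung, residual)))
    return cohort


# --------------------------------------------------------------------------
# voxel phantom
# --------------------------------------------------------------------------


def default_grid(spacing: float = 4.0) -> GridSpec:
    """Default head-to-thigh grid: ~38 x 32 x 104 cm field of view."""
    scale = 4.0 / spacing
    shape = (int(round(96 * scale)), int(round(80 * scale)), int(round(260 * scale)))
    return GridSpec(shape, (spacing, spacing, spacing))


def _normalized_coords(shape: tuple[int, int, int]) -> list[np.ndarray]:
    """Per-axis voxel coordinates rescaled to [-1, 1] across the grid."""
    return [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) / (n / 2.0)
        for n in shape
    ]


# Lung placement in normalized body coordinates: two ellipsoids offset
# laterally (axis 0) in the upper chest (axis 2 toward +1 = head).
_LUNG_CENTERS = ((-0.35, 0.0, 0.45), (0.35, 0.0, 0.45))
_LUNG_SEMI_AXES = (0.30, 0.55, 0.28)


def build_phantom(
    composition: BodyComposition,
    grid: GridSpec,
    densities: dict[str, float] | None = None,
) -> tuple[AttenuationMap, CompartmentLabelMap]:
    """Voxel phantom realising a body composition on a grid.

    Geometry: a quasi-ellipsoidal body of water voxels wearing a fat shell,
    with two lung regions in the upper chest, in an air background. Exact
    per-compartment voxel counts are guaranteed by rank-order selection
    (voxels sorted by an ellipsoidal norm), so count x voxel volume x nominal
    density matches each compartment mass to within half a voxel-mass.

    Raises :class:`ConfigurationError` if the requested volumes do not fit.
    """
    densities = densities or NOMINAL_DENSITIES
    vox_l = grid.voxel_volume_l
    counts = {
        name: int(round(getattr(composition, f"{name}_mass") / densities[name] / vox_l))
        for name in ("water", "fat", "lung")
    }
    n_body = sum(counts.values())
    if n_body > grid.size:
        raise ConfigurationError(
            f"body needs {n_body} voxels but the grid holds only {grid.size}; "
            "enlarge the grid or coarsen the spacing"
        )

    u = _normalized_coords(grid.shape)
    body_r2 = (
        u[0][:, None, None] ** 2 + u[1][None, :, None] ** 2 + u[2][None, None, :] ** 2
    ).ravel()
    order = np.argsort(body_r2, kind="stable")
    body = order[:n_body]
    # Fat shell = outermost body voxels; interior gets lungs then water.
    interior = body[: n_body - counts["fat"]]
    fat_idx = body[n_body - counts["fat"]:]

    lung_r2 = np.full(grid.size, np.inf)
    for cx, cy, cz in _LUNG_CENTERS:
        r2 = (
            ((u[0][:, None, None] - cx) / _LUNG_SEMI_AXES[0]) ** 2
            + ((u[1][None, :, None] - cy) / _LUNG_SEMI_AXES[1]) ** 2
            + ((u[2][None, None, :] - cz) / _LUNG_SEMI_AXES[2]) ** 2
        ).ravel()
        np.minimum(lung_r2, r2, out=lung_r2)
    lung_order = np.argsort(lung_r2[interior], kind="stable")
    lung_idx = interior[lung_order[: counts["lung"]]]
    water_idx = interior[lung_order[counts["lung"]:]]

    labels = np.full(grid.size, LABEL_CODES["air"], dtype=np.int8)
    labels[lung_idx] = LABEL_CODES["lung"]
    labels[fat_idx] = LABEL_CODES["fat"]
    labels[water_idx] = LABEL_CODES["water"]
    labels = labels.reshape(grid.shape)

    mu = np.zeros(grid.shape, dtype=np.float64)
    for name, code in LABEL_CODES.items():
        mu[labels == code] = MU_VALUES[name]

    return (
        AttenuationMap(mu, grid.spacing, grid.origin),
        CompartmentLabelMap(labels, grid.spacing, grid.origin),
    )


# --------------------------------------------------------------------------
# DXA simulation
# --------------------------------------------------------------------------


def simulate_dxa(
    composition: BodyComposition,
    coverage_fraction: float | dict[str, float] = 1.0,
    noise_cv: float = 0.02,
    seed: int = 0,
    subject_id: str = "",
) -> DXARecord:
    """DXA-style fat / non-fat masses: coverage-scaled truth with
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``.

    ``coverage_fraction`` is a scalar or a per-compartment dict with keys
    among {"fat", "water", "lung"}; the composition's compartments already
    exclude off-coverage (residual) mass, so coverage 1.0 corresponds to the
    head-to-thigh scan region.
    """
    if isinstance(coverage_fraction, dict):
        cov = {k: float(coverage_fraction.get(k, 1.0)) for k in ("fat", "water", "lung")}
    else:
        cov = {k: float(coverage_fraction) for k in ("fat", "water", "lung")}
    for k, v in cov.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"coverage_fraction[{k!r}] must be in [0, 1], got {v}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    rng = np.random.default_rng(seed)
    fat = composition.fat_mass * cov["fat"]
    nonfat = composition.water_mass * cov["water"] + composition.lung_mass * cov["lung"]
    if noise_cv > 0:
        fat *= 1.0 + noise_cv * rng.standard_normal()
        nonfat *= 1.0 + noise_cv * rng.standard_normal()
    return DXARecord(
        subject_id=subject_id,
        fat_mass=max(fat, 0.0),
        nonfat_mass=max(nonfat, 0.0),
        coverage="head_to_thigh",
    )


# --------------------------------------------------------------------------
# PET simulation
# --------------------------------------------------------------------------

#: Organ uptake levels on the lean-mass SUV scale (an organ at level L has
#: lean-normalized SUV ~= L under perfect calibration). FDG levels mimic the
#: whole-body FDG pattern: hot brain, moderate liver, low blood/muscle.
DEFAULT_UPTAKE_FDG: dict[str, float] = {
    "brain": 3.7,
    "liver": 1.0,
    "blood": 0.58,
    "muscle": 0.35,
    "background": 0.30,
    "lung": 0.20,
    "fat": 0.0,
}

#: PSMA-style pattern: hot parotid, warm liver/prostate, cold background.
DEFAULT_UPTAKE_PSMA: dict[str, float] = {
    "parotid": 7.0,
    "liver": 4.8,
    "prostate": 4.0,
    "blood": 0.37,
    "muscle": 0.22,
    "background": 0.20,
    "lung": 0.15,
    "fat": 0.0,
}

_KNOWN_ORGANS = {
    "brain", "liver", "blood", "muscle", "prostate", "parotid",
    "background", "lung", "fat",
}

# Anchor points (normalized body coordinates) and diameters (mm) of the
# spherical organ regions carved out of the water compartment.
_SPHERE_ORGANS: dict[str, tuple[tuple[float, float, float], float]] = {
    "liver": ((0.30, 0.0, 0.10), 90.0),
    "blood": ((0.0, 0.0, 0.45), 30.0),
    "prostate": ((0.0, 0.0, -0.55), 40.0),
}
# Organs taken as the extreme-z slab of water voxels:
# (toward head?, litres, z-gate in normalized coordinates). The gate keeps a
# small subject's "brain" from descending into the chest and swallowing the
# blood pool; if a body is so small that no water lies past the gate, the
# gate is dropped and the plain extreme-z slab used.
_SLAB_ORGANS: dict[str, tuple[bool, float, float]] = {
    "brain": (True, 1.2, 0.5),
    "parotid": (True, 0.1, 0.5),
    "muscle": (False, 0.35, -0.5),
}


def _norm_to_world(grid: GridSpec, cnorm: tuple[float, float, float]) -> tuple[float, ...]:
    return tuple(
        grid.origin[a] + grid.spacing[a] * (cnorm[a] * grid.shape[a] / 2.0 + (grid.shape[a] - 1) / 2.0)
        for a in range(3)
    )


def _place_organs(
    labels: CompartmentLabelMap, organs: list[str]
) -> tuple[dict[str, np.ndarray], dict[str, tuple[float, ...]]]:
    """Carve disjoint organ voxel sets out of the water compartment."""
    grid = labels.gridspec
    water_flat = np.flatnonzero(labels.grid.ravel() == LABEL_CODES["water"])
    taken = np.zeros(grid.size, dtype=bool)
    truth: dict[str, np.ndarray] = {}
    centers: dict[str, tuple[float, ...]] = {}

    # Slab organs first (brain before parotid so the parotid sits just below),
    # then spheres; later claims exclude already-taken voxels.
    for organ in organs:
        if organ in _SLAB_ORGANS:
            toward_head, litres, z_gate = _SLAB_ORGANS[organ]
            n_vox = max(1, int(round(litres / grid.voxel_volume_l)))
            free = water_flat[~taken[water_flat]]
            zf = np.unravel_index(free, grid.shape)[2]
            z_norm = (zf - (grid.shape[2] - 1) / 2.0) / (grid.shape[2] / 2.0)
            gated = free[z_norm >= z_gate] if toward_head else free[z_norm <= z_gate]
            pool = gated if gated.size else free
            zp = np.unravel_index(pool, grid.shape)[2]
            order = np.argsort(-zp if toward_head else zp, kind="stable")
            chosen = pool[order[:n_vox]]
        elif organ in _SPHERE_ORGANS:
            cnorm, diameter = _SPHERE_ORGANS[organ]
            center = _norm_to_world(grid, cnorm)
            sphere = sphere_roi(grid, center, diameter)
            in_water = sphere[(labels.grid.ravel()[sphere] == LABEL_CODES["water"]) & ~taken[sphere]]
            if in_water.size == 0:
                raise ConfigurationError(
                    f"organ {organ!r} sphere at {center} contains no free water voxels"
                )
            chosen = in_water
            centers[organ] = center
        else:
            continue  # background / lung / fat are whole compartments
        truth[organ] = chosen
        taken[chosen] = True
    return truth, centers


def simulate_pet(
    labels: CompartmentLabelMap,
    subject: SubjectRecord,
    composition: BodyComposition,
    uptake_profile: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    organ_cv: float = 0.0,
) -> ActivityImage:
    """Forward-simulate a PET activity map (kBq/mL) on a phantom.

    Each organ's activity concentration is ``level * dose * decay_factor /
    lean_reference_mass`` (lean reference = water + lung mass), so the
    lean-normalized SUV of an organ recovers its level. Fat voxels have
    exactly zero uptake before noise. ``organ_cv`` adds per-organ lognormal
    biological variability (median-preserving); ``noise_sd`` adds voxelwise
    zero-mean Gaussian noise, clipped at zero to keep activity nonnegative.
    """
    uptake = dict(DEFAULT_UPTAKE_FDG if uptake_profile is None else uptake_profile)
    unknown = set(uptake) - _KNOWN_ORGANS
    if unknown:
        raise ValueError(f"unknown organs in uptake profile: {sorted(unknown)}")
    for organ, level in uptake.items():
        if level < 0:
            raise ValueError(f"uptake level for {organ!r} must be >= 0, got {level}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    grid = labels.gridspec
    scale = (
        subject.injected_dose
        * decay_factor(subject.wait_time, subject.half_life)
        / composition.lean_reference_mass
    )

    bio = {
        organ: float(np.exp(organ_cv * rng.standard_normal())) if organ_cv > 0 else 1.0
        for organ in sorted(uptake)
    }

    activity = np.zeros(grid.size, dtype=np.float64)
    flat_labels = labels.grid.ravel()
    activity[flat_labels == LABEL_CODES["water"]] = (
        uptake.get("background", 0.0) * bio.get("background", 1.0) * scale
    )
    activity[flat_labels == LABEL_CODES["lung"]] = (
        uptake.get("lung", 0.0) * bio.get("lung", 1.0) * scale
    )
    # fat and air stay at zero

    focal = [o for o in uptake if o in _SPHERE_ORGANS or o in _SLAB_ORGANS]
    order = [o for o in ("brain", "parotid", "muscle", "liver", "blood", "prostate") if o in focal]
    truth, centers = _place_organs(labels, order)
    for organ in order:
        activity[truth[organ]] = uptake[organ] * bio[organ] * scale

    if noise_sd > 0:
        activity += noise_sd * rng.standard_normal(activity.size)
        np.clip(activity, 0.0, None, out=activity)

    return ActivityImage(
        grid=activity.reshape(grid.shape),
        spacing=grid.spacing,
        origin=grid.origin,
        organ_truth=truth,
        organ_centers=centers,
    )
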