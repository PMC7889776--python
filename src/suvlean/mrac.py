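"""Dixon MRAC volumetrics and DXA density calibration.

The four-class MR attenuation-correction map assigns each voxel one of four
linear attenuation coefficients (water 0.096, fat 0.08, lung 0.032, air 0
cm^-1). Segmentation here simply inverts that assignment: each voxel is
mapped to the nearest label constant, with a strict tolerance so corrupt maps
fail loudly instead of silently mislabeling tissue.

Compartment volumes (voxel count x voxel volume) are converted to masses via
per-tissue densities (kg/L) calibrated against DXA:

* simple mode — two univariate zero-intercept fits, DXA fat mass on fat
  volume and DXA non-fat mass on water volume;
* multi mode — one zero-intercept multiple regression of DXA-covered total
  mass on (fat, water, lung) volumes, whose coefficients are directly
  interpretable as tissue densities.

The Dixon lean fraction is then water_mass / (water + fat + lung mass),
the factor that converts SUVbw to SUV_dixon. Air carries no mass.
"""

from __future__ import annotations

import numpy as np

from .errors import FitError, SegmentationError
from .types import (
    AttenuationMap,
    CompartmentLabelMap,
    CompartmentVolumes,
    DensityCalibration,
    DXARecord,
    LABEL_CODES,
    MU_VALUES,
)

#: Default tolerance (cm^-1) for nearest-label assignment: comfortably below
#: half the smallest inter-label gap (water-fat: 0.016).
DEFAULT_TOLERANCE = 0.004

_LABEL_NAMES = list(MU_VALUES)  # air, lung, fat, water
_MU_ARRAY = np.array([MU_VALUES[n] for n in _LABEL_NAMES])
_CODE_ARRAY = np.array([LABEL_CODES[n] for n in _LABEL_NAMES], dtype=np.int8)


def segment_mrac(attn: AttenuationMap, tolerance: float = DEFAULT_TOLERANCE) -> CompartmentLabelMap:
    """Assign each voxel the nearest attenuation label constant.

    Raises :class:`SegmentationError` naming the first offending value if any
    voxel is farther than ``tolerance`` from every label constant.
    """
    if not 0 < tolerance < 0.008:
        raise ValueError(
            f"tolerance must be in (0, 0.008) cm^-1 (half the minimum label gap), got {tolerance!r}"
        )
    values = attn.grid.reshape(-1, 1)
    dist = np.abs(values - _MU_ARRAY[None, :])
    nearest = np.argmin(dist, axis=1)
    mindist = dist[np.arange(dist.shape[0]), nearest]
    bad = mindist > tolerance
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise SegmentationError(
            f"voxel value {values[i, 0]:.6g} cm^-1 at flat index {i} is "
            f"{mindist[i]:.6g} from the nearest label constant "
            f"({_MU_ARRAY[nearest[i]]:.3g}), beyond tolerance {tolerance:g}"
        )
    labels = _CODE_ARRAY[nearest].reshape(attn.grid.shape)
    return CompartmentLabelMap(labels, attn.spacing, attn.origin)


def compartment_volumes(labels: CompartmentLabelMap) -> CompartmentVolumes:
    """Volume per compartment in litres: label count x voxel volume."""
    vox_l = labels.gridspec.voxel_volume_l
    return CompartmentVolumes(
        water_volume=labels.count("water") * vox_l,
        fat_volume=labels.count("fat") * vox_l,
        lung_volume=labels.count("lung") * vox_l,
        air_volume=labels.count("air") * vox_l,
    )


def _zero_intercept_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Univariate least squares through the origin.

    Returns (slope, uncentered r^2, standard error of the slope).
    """
    sxx = float(x @ x)
    if sxx == 0.0:
        raise FitError("regressor is identically zero")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    n = x.size
    sigma2 = ss_res / (n - 1) if n > 1 else 0.0
    return slope, r2, float(np.sqrt(sigma2 / sxx))


def fit_density_simple(pairs: list[tuple[CompartmentVolumes, DXARecord]]) -> dict[str, float]:
    """Univariate zero-intercept fits of DXA mass on MRAC volume.

    Fits DXA fat mass on fat volume and DXA non-fat mass on water volume;
    returns ``{"slope_fat", "r2_fat", "se_fat", "slope_water", "r2_water",
    "se_water", "n"}`` with slopes in kg/L.
    """
    if len(pairs) < 3:
        raise FitError(f"need at least 3 subjects, got {len(pairs)}")
    fat_v = np.array([v.fat_volume for v, _ in pairs])
    wat_v = np.array([v.water_volume for v, _ in pairs])
    fat_m = np.array([d.fat_mass for _, d in pairs])
    nonfat_m = np.array([d.nonfat_mass for _, d in pairs])
    slope_fat, r2_fat, se_fat = _zero_intercept_fit(fat_v, fat_m)
    slope_water, r2_water, se_water = _zero_intercept_fit(wat_v, nonfat_m)
    return {
        "slope_fat": slope_fat,
        "r2_fat": r2_fat,
        "se_fat": se_fat,
        "slope_water": slope_water,
        "r2_water": r2_water,
        "se_water": se_water,
        "n": len(pairs),
    }


def fit_density_multi(pairs: list[tuple[CompartmentVolumes, DXARecord]]) -> DensityCalibration:
    """Zero-intercept multiple regression of DXA-covered total mass on
    (fat, water, lung) volumes; the coefficients are tissue densities (kg/L).

    Raises :class:`FitError` on fewer than 4 subjects or a rank-deficient
    volume design matrix.
    """
    if len(pairs) < 4:
        raise FitError(f"need at least 4 subjects, got {len(pairs)}")
    X = np.array([[v.fat_volume, v.water_volume, v.lung_volume] for v, _ in pairs])
    y = np.array([d.total_mass for _, d in pairs])
    if np.linalg.matrix_rank(X) < 3:
        raise FitError("volume design matrix (fat, water, lung) is rank-deficient")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    n, p = X.shape
    sigma2 = ss_res / (n - p) if n > p else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return DensityCalibration(
        density_fat=float(coef[0]),
        density_water=float(coef[1]),
        density_lung=float(coef[2]),
        mode="multi",
        r_squared={"total_mass": 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0},
        std_errors={"fat": float(se[0]), "water": float(se[1]), "lung": float(se[2])},
        n=n,
    )


def dixon_lean_fraction(
    volumes: CompartmentVolumes,
    cal: DensityCalibration,
    lung_in_numerator: bool = False,
) -> float:
    """Dixon lean fraction: water mass / (water + fat + lung mass).

    Masses are density x volume from the calibration. With
    ``lung_in_numerator`` the numerator becomes water + lung mass (the
    alternative reading under which lung counts as lean tissue).
    """
    m_water = cal.density_water * volumes.water_volume
    m_fat = cal.density_fat * volumes.fat_volume
    m_lung = cal.density_lung * volumes.lung_volume
    denom = m_water + m_fat + m_lung
    if denom == 0.0:
        raise ValueError("lean fraction undefined: all compartment masses are zero")
    num = m_water + m_lung if lung_in_numerator else m_water
    return num / denom
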