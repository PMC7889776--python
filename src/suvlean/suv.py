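"""SUV computation and ROI quantitation.

SUV normalized to body weight::

    SUVbw = C / (D * DF / BW)

with C the ROI activity concentration (kBq/mL), D the injected dose (MBq),
BW the body weight (kg) and DF = exp(-0.693 * wait / half_life) the physical
decay factor. The MBq->kBq and kg->g conversions cancel, leaving SUV in g/mL.

Lean normalizations rescale SUVbw by a lean-mass fraction:

* ``suv_dixon = SUVbw * water_mass / (water + fat + lung mass)`` with masses
  from calibrated MRAC volumetrics,
* ``suv_james = SUVbw * LBM_james / BW``,
* ``suv_janma = SUVbw * LBM_janma / BW``.

ROI conventions follow PERCIST-style quantitation: spherical ROIs include
every voxel whose center lies within the radius; SUVpeak is the mean over a
1 cm^3 sphere centered on the SUVmax voxel.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .errors import EmptyROIError
from .types import GridSpec, LBMEstimate, SUVMeasurement

#: The decay-factor constant; 0.693 is the conventional rounding of ln 2.
DECAY_CONSTANT = 0.693

#: Diameter (mm) of a 1 cm^3 sphere, used by SUVpeak.
PEAK_SPHERE_DIAMETER_MM = 2.0 * (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def decay_factor(wait_time: float, half_life: float, constant: float = DECAY_CONSTANT) -> float:
    """exp(-constant * wait_time / half_life); dimensionless in (0, 1]."""
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    if wait_time < 0:
        raise ValueError("wait_time must be >= 0")
    return math.exp(-constant * wait_time / half_life)


def suv_bw(
    activity,
    dose: float,
    wait_time: float,
    half_life: float,
    weight: float,
    constant: float = DECAY_CONSTANT,
):
    """Body-weight SUV (g/mL) of an activity concentration in kBq/mL.

    ``activity`` may be a scalar or an array (elementwise conversion of a
    whole image). dose in MBq, weight in kg.
    """
    if dose <= 0 or weight <= 0:
        raise ValueError("dose and weight must be > 0")
    df = decay_factor(wait_time, half_life, constant)
    # activity[kBq/mL] / (dose[MBq]*1000[kBq/MBq] * DF / (weight[kg]*1000[g/kg]))
    out = np.asarray(activity, dtype=np.float64) * weight / (dose * df)
    return float(out) if out.ndim == 0 else out


def _voxel_centers_axis(n: int, spacing: float, origin: float) -> np.ndarray:
    return origin + spacing * np.arange(n)


def sphere_roi(grid: GridSpec, center, diameter: float) -> np.ndarray:
    """Flat indices of voxels whose centers lie within ``diameter/2`` of
    ``center`` (world mm). Raises :class:`EmptyROIError` if none do."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    r2 = (diameter / 2.0) ** 2
    axes = [
        (_voxel_centers_axis(grid.shape[i], grid.spacing[i], grid.origin[i]) - center[i]) ** 2
        for i in range(3)
    ]
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    idx = np.flatnonzero(d2.ravel() <= r2)
    if idx.size == 0:
        raise EmptyROIError(
            f"sphere of diameter {diameter} mm at {tuple(center)} contains no voxel centers"
        )
    return idx


def threshold_roi(image: np.ndarray, threshold: float) -> np.ndarray:
    """Flat indices of voxels with value strictly above ``threshold``.

    An empty result is allowed (returned empty with a warning) — thresholding
    a cold image is a legitimate, flaggable outcome.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    idx = np.flatnonzero(np.asarray(image).ravel() > threshold)
    if idx.size == 0:
        warnings.warn(
            f"threshold {threshold} exceeds every voxel value; ROI is empty",
            UserWarning,
            stacklevel=2,
        )
    return idx


def roi_statistics(image: np.ndarray, roi: np.ndarray) -> tuple[float, float]:
    """(max, mean) of the image over the ROI's flat indices."""
    roi = np.asarray(roi)
    if roi.size == 0:
        raise EmptyROIError("cannot compute statistics of an empty ROI")
    vals = np.asarray(image, dtype=np.float64).ravel()[roi]
    return float(vals.max()), float(vals.mean())


def suv_peak(
    image: np.ndarray,
    grid: GridSpec,
    search_roi: np.ndarray,
    diameter: float = PEAK_SPHERE_DIAMETER_MM,
    optimize_position: bool = False,
) -> float:
    """Mean SUV in a 1 cm^3 sphere around the hottest voxel of ``search_roi``.

    By default the sphere is centered on the SUVmax voxel. With
    ``optimize_position`` the sphere center is instead swept over every voxel
    of the search ROI and the largest sphere-mean returned.
    """
    search_roi = np.asarray(search_roi)
    if search_roi.size == 0:
        raise EmptyROIError("SUVpeak needs a nonempty search ROI")
    flat = np.asarray(image, dtype=np.float64).ravel()

    def sphere_mean_at(flat_index: int) -> float:
        ijk = np.unravel_index(int(flat_index), grid.shape)
        center = [grid.origin[a] + grid.spacing[a] * ijk[a] for a in range(3)]
        sph = sphere_roi(grid, center, diameter)
        return float(flat[sph].mean())

    if not optimize_position:
        hottest = search_roi[int(np.argmax(flat[search_roi]))]
        return sphere_mean_at(hottest)
    return max(sphere_mean_at(i) for i in search_roi)


def apply_lbm_correction(
    suv_bw_value: float,
    estimates: dict[str, LBMEstimate],
    weight: float,
    dixon_fraction: float,
    organ: str = "",
    statistic: str = "mean",
) -> SUVMeasurement:
    """Build an :class:`SUVMeasurement` from a body-weight SUV.

    ``estimates`` must contain 'james' and 'janma'; ``dixon_fraction`` is the
    Dixon lean fraction water/(water+fat+lung) as a unitless value in (0, 1.2]
    (the upper slack admits mild calibration overshoot).
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if not 0 < dixon_fraction <= 1.2:
        raise ValueError(f"dixon_fraction {dixon_fraction!r} outside the sane range (0, 1.2]")
    for method in ("james", "janma"):
        if method not in estimates:
            raise KeyError(f"missing LBM estimate for method {method!r}")
    return SUVMeasurement(
        organ=organ,
        statistic=statistic,
        suv_bw=suv_bw_value,
        suv_dixon=suv_bw_value * dixon_fraction,
        suv_james=suv_bw_value * estimates["james"].lbm / weight,
        suv_janma=suv_bw_value * estimates["janma"].lbm / weight,
    )
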