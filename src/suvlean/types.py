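"""Domain types shared across the package.

Conventions
-----------
* Lengths in mm on image grids, heights in cm (clinical convention), masses in
  kg, volumes in L, activity concentration in kBq/mL, injected dose in MBq,
  times in minutes.
* Voxel world coordinate = ``origin + index * spacing`` (nibabel diagonal
  affine convention); a voxel's value is taken to live at that point.
* Attenuation-label maps are stored as int8 codes; the code <-> name mapping
  and the four MRAC attenuation constants live here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

# Four-class MRAC attenuation constants (cm^-1): air, lung, fat, water.
MU_VALUES: dict[str, float] = {"air": 0.0, "lung": 0.032, "fat": 0.08, "water": 0.096}
LABEL_CODES: dict[str, int] = {"air": 0, "lung": 1, "fat": 2, "water": 3}
CODE_NAMES: dict[int, str] = {v: k for k, v in LABEL_CODES.items()}

#: F-18 physical half-life in minutes.
F18_HALF_LIFE_MIN: float = 109.77

#: Nominal tissue densities (kg/L) used by the synthetic generator:
#: fat, water(-equivalent soft tissue), lung.
NOMINAL_DENSITIES: dict[str, float] = {"fat": 0.79, "water": 1.23, "lung": 0.20}


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass
class SubjectRecord:
    """Demographics, dose and timing for one subject.

    ``bmi`` may be omitted (None) and is then derived from weight and height;
    if given it must be consistent with weight/(height/100)^2 within 0.01.
    """

    subject_id: str
    sex: str  # "M" or "F"
    height: float  # cm
    weight: float  # kg
    injected_dose: float  # MBq
    wait_time: float  # min
    bmi: float | None = None
    half_life: float = F18_HALF_LIFE_MIN  # min
    tracer: str = "FDG"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.tracer not in ("FDG", "PSMA"):
            raise ValueError(f"tracer must be 'FDG' or 'PSMA', got {self.tracer!r}")
        for name in ("height", "weight", "injected_dose", "half_life"):
            _positive(name, getattr(self, name))
        if self.wait_time < 0:
            raise ValueError(f"wait_time must be >= 0, got {self.wait_time!r}")
        derived = self.weight / (self.height / 100.0) ** 2
        if self.bmi is None:
            self.bmi = derived
        elif abs(self.bmi - derived) > 0.01:
            raise ValueError(
                f"bmi {self.bmi:.4f} inconsistent with weight/height^2 = {derived:.4f}"
            )


@dataclass
class BodyComposition:
    """Ground-truth mass decomposition of one subject.

    ``residual_mass`` is mass outside the imaged (head-to-thigh) coverage; the
    three imaged compartments plus residual sum to the subject weight.
    """

    water_mass: float  # kg
    fat_mass: float  # kg
    lung_mass: float  # kg
    residual_mass: float  # kg

    def __post_init__(self) -> None:
        for name in ("water_mass", "fat_mass", "lung_mass", "residual_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_mass(self) -> float:
        return self.water_mass + self.fat_mass + self.lung_mass + self.residual_mass

    @property
    def covered_mass(self) -> float:
        """Mass inside imaging coverage (water + fat + lung)."""
        return self.water_mass + self.fat_mass + self.lung_mass

    @property
    def lean_reference_mass(self) -> float:
        """Non-fat mass inside coverage (water + lung); the generator's
        lean mass against which tracer dose is distributed."""
        return self.water_mass + self.lung_mass


@dataclass
class GridSpec:
    """Shape (voxels), spacing (mm per axis) and world origin (mm) of a grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape!r}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing!r}")
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_l(self) -> float:
        return self.voxel_volume_mm3 / 1.0e6  # 1 L = 1e6 mm^3


@dataclass
class AttenuationMap:
    """3D linear-attenuation-coefficient map (cm^-1)."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("attenuation grid must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on every axis")

    @property
    def gridspec(self) -> GridSpec:
        return GridSpec(self.grid.shape, self.spacing, self.origin)


@dataclass
class CompartmentLabelMap:
    """3D map of tissue labels; every voxel carries exactly one of
    {air, lung, fat, water} (int8 codes per :data:`LABEL_CODES`)."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3D")
        bad = set(np.unique(self.grid)) - set(CODE_NAMES)
        if bad:
            raise ValueError(f"unknown label codes {sorted(bad)}")

    @property
    def gridspec(self) -> GridSpec:
        return GridSpec(self.grid.shape, self.spacing, self.origin)

    def mask(self, label: str) -> np.ndarray:
        return self.grid == LABEL_CODES[label]

    def count(self, label: str) -> int:
        return int(np.count_nonzero(self.mask(label)))


@dataclass
class CompartmentVolumes:
    """Per-compartment volumes in litres (voxel count x voxel volume)."""

    water_volume: float
    fat_volume: float
    lung_volume: float
    air_volume: float

    def __post_init__(self) -> None:
        for name in ("water_volume", "fat_volume", "lung_volume", "air_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.water_volume + self.fat_volume + self.lung_volume + self.air_volume


@dataclass
class DXARecord:
    """DXA-style fat / non-fat mass measurement for one subject (kg)."""

    subject_id: str
    fat_mass: float
    nonfat_mass: float
    coverage: str = "head_to_thigh"  # or "whole_body"

    def __post_init__(self) -> None:
        if self.fat_mass < 0 or self.nonfat_mass < 0:
            raise ValueError("DXA masses must be >= 0")
        if self.coverage not in ("head_to_thigh", "whole_body"):
            raise ValueError(f"unknown coverage {self.coverage!r}")

    @property
    def total_mass(self) -> float:
        return self.fat_mass + self.nonfat_mass


@dataclass
class ActivityImage:
    """3D PET activity-concentration image (kBq/mL) with ground-truth organ
    voxel sets (flat indices into ``grid``; mutually disjoint)."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ_truth: dict[str, np.ndarray] = field(default_factory=dict)
    organ_centers: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("activity grid must be 3D")
        if np.any(self.grid < 0):
            raise ValueError("activity must be >= 0 everywhere")
        seen: set[int] = set()
        for organ, idx in self.organ_truth.items():
            s = set(int(i) for i in np.asarray(idx).ravel())
            if seen & s:
                raise ValueError(f"organ_truth sets are not disjoint at {organ!r}")
            seen |= s

    @property
    def gridspec(self) -> GridSpec:
        return GridSpec(self.grid.shape, self.spacing, self.origin)


@dataclass
class DensityCalibration:
    """Mass-per-volume coefficients (kg/L) relating MRAC compartment volumes
    to DXA masses, with fit diagnostics."""

    density_fat: float
    density_water: float
    density_lung: float
    mode: str  # "simple" or "multi"
    r_squared: dict[str, float] = field(default_factory=dict)
    std_errors: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simple", "multi", "nominal"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        # A noisy regression may return a nonpositive coefficient for a
        # weakly identified compartment (lung volume varies little across
        # subjects); represent it faithfully but warn — downstream mass
        # computations will refuse to use it.
        for name in ("density_fat", "density_water", "density_lung"):
            if getattr(self, name) <= 0:
                warnings.warn(
                    f"{name} = {getattr(self, name):.4g} kg/L is nonpositive; "
                    "the fit is weakly identified for this compartment",
                    UserWarning,
                    stacklevel=2,
                )

    @classmethod
    def nominal(cls) -> "DensityCalibration":
        """The generator's nominal densities, usable when no DXA data exist."""
        d = NOMINAL_DENSITIES
        return cls(d["fat"], d["water"], d["lung"], mode="nominal")


@dataclass
class LBMEstimate:
    """Lean body mass for one subject by one method.

    ``fraction`` is percent of total body weight. ``flagged`` marks
    out-of-model results (the James formula goes negative at extreme BMI);
    the value is reported as-is, never clipped.
    """

    method: str  # dixon | james | janma | dxa
    lbm: float  # kg
    fraction: float  # percent of body weight
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("dixon", "james", "janma", "dxa"):
            raise ValueError(f"unknown LBM method {self.method!r}")


@dataclass
class ROISpec:
    """Declarative region-of-interest: a sphere (center mm, diameter mm) or a
    threshold rule (in SUV units)."""

    kind: str  # "sphere" | "threshold"
    organ: str
    center: tuple[float, float, float] | None = None
    diameter: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "sphere":
            if self.center is None or self.diameter is None or self.diameter <= 0:
                raise ValueError("sphere ROI needs a center and a positive diameter")
        elif self.kind == "threshold":
            if self.threshold is None or self.threshold < 0:
                raise ValueError("threshold ROI needs a threshold >= 0")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")


@dataclass
class SUVMeasurement:
    """One ROI statistic with body-weight and all three lean normalizations."""

    organ: str
    statistic: str  # max | mean | peak
    suv_bw: float
    suv_dixon: float
    suv_james: float
    suv_janma: float

    def __post_init__(self) -> None:
        if self.statistic not in ("max", "mean", "peak"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


def bmi_from(weight: float, height_cm: float) -> float:
    """BMI = weight / (height in m)^2."""
    _positive("weight", weight)
    _positive("height", height_cm)
    return weight / (height_cm / 100.0) ** 2


def nearly_equal(a: float, b: float, tol: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=tol, abs_tol=tol)
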