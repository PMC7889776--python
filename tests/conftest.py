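"""Shared fixtures: a small cohort and a coarse phantom.

Everything is generated at test time from seeded generators; no data files.
Coarse 8 mm grids keep phantom construction fast while preserving every
structural property (exact label constants, compartment counts, organ sets).
"""

import numpy as np
import pytest

from suvlean.mrac import segment_mrac
from suvlean.synthetic import build_phantom, default_grid, generate_cohort
from suvlean.types import NOMINAL_DENSITIES, BodyComposition, CompartmentVolumes


@pytest.fixture(scope="session")
def cohort8():
    return generate_cohort(8, seed=3)


@pytest.fixture(scope="session")
def coarse_grid():
    return default_grid(8.0)


@pytest.fixture(scope="session")
def phantom(cohort8, coarse_grid):
    subject, composition = cohort8[0]
    attn, labels = build_phantom(composition, coarse_grid)
    return subject, composition, attn, labels


@pytest.fixture(scope="session")
def reference_composition():
    """A composition with the cohort-mean water/fat masses and a nominal
    lung; residual chosen to make an 8%-residual 63 kg-scale subject."""
    return BodyComposition(
        water_mass=33.50, fat_mass=17.38, lung_mass=0.60, residual_mass=4.48
    )


def exact_volumes(composition: BodyComposition) -> CompartmentVolumes:
    """Noise-free volumes implied by a composition at the nominal densities
    (the analytic inverse of the phantom voxelization)."""
    d = NOMINAL_DENSITIES
    return CompartmentVolumes(
        water_volume=composition.water_mass / d["water"],
        fat_volume=composition.fat_mass / d["fat"],
        lung_volume=composition.lung_mass / d["lung"],
        air_volume=0.0,
    )


@pytest.fixture(scope="session")
def segmented(phantom):
    _, _, attn, labels = phantom
    seg = segment_mrac(attn)
    assert np.array_equal(seg.grid, labels.grid)
    return seg
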