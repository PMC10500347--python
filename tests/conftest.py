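"""Shared fixtures: analytic phantoms and a small synthetic population."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from octraman import morpho
from octraman.synth import (
    CLASS_LABELS,
    SyntheticCellParams,
    default_class_profiles,
    generate_cell_volume,
    generate_population,
)
from octraman.types import LabelMap

PAPER_SPACING = (0.45, 0.45, 0.2)


@pytest.fixture(scope="session")
def paper_spacing():
    return PAPER_SPACING


@pytest.fixture(scope="session")
def sphere10(paper_spacing):
    """A voxelised 10 µm-radius sphere of constant interior 100, no noise."""
    params = SyntheticCellParams(radius_um=10.0, interior_mean=100.0)
    vol, truth = generate_cell_volume(params, paper_spacing, (115, 52, 52), seed=1)
    return vol, truth


@pytest.fixture(scope="session")
def cube10(paper_spacing):
    """An axis-aligned 10 µm cube label map."""
    dx, dy, dz = paper_spacing
    nzc, nyc = round(10.0 / dz), round(10.0 / dy)
    mask = np.zeros((nzc + 10, nyc + 6, nyc + 6), dtype=np.int32)
    mask[5 : 5 + nzc, 3 : 3 + nyc, 3 : 3 + nyc] = 1
    return LabelMap(mask, paper_spacing)


@pytest.fixture(scope="session")
def hemisphere10(paper_spacing):
    """A 10 µm-radius hemisphere, flat side down (deep z), dome toward z=0."""
    dx, dy, dz = paper_spacing
    R = 10.0
    nz, ny, nx = 58, 50, 50
    z = np.arange(nz) * dz
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    zc = 10.5
    mask = (X**2 + Y**2 + (Z - zc) ** 2 <= R * R) & (Z <= zc)
    return LabelMap(mask.astype(np.int32), paper_spacing)


def population_features(n_per_class: int, seed: int) -> pd.DataFrame:
    """Generate the default population and extract ground-truth features."""
    pop = generate_population(
        default_class_profiles(), {c: n_per_class for c in CLASS_LABELS}, seed=seed
    )
    frames = [
        morpho.features_to_frame(
            morpho.extract_features(vol, truth.label_map, truth), volume_id=f"v{i:03d}"
        )
        for i, (vol, truth) in enumerate(pop)
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_population_features():
    """12 cells per class, ground-truth label maps: enough for ordering and
    significance checks while staying fast."""
    return population_features(12, seed=3)
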