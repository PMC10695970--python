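"""Shared fixtures: desk-scale default population and a small rendered scene."""

from __future__ import annotations

import numpy as np
import pytest

from obliquescale.core import CellTable
from obliquescale.preprocess import ShearGeometry
from obliquescale.synthetic import (
    GroundTruth,
    MovieNoiseModel,
    PopulationConfig,
    generate_cell_positions,
    generate_population_activity,
    generate_volume_movie,
)


@pytest.fixture(scope="session")
def default_population() -> tuple[GroundTruth, CellTable]:
    """The desk-scale default synthetic population: 3,000 cells, 38 min at
    1 Hz, 400 latent factors, decay exponent 0.28."""
    cfg = PopulationConfig(seed=0)
    truth = generate_population_activity(generate_cell_positions(cfg), cfg)
    return truth, truth.to_cell_table()


def _spaced_positions(
    n: int, low: np.ndarray, high: np.ndarray, min_sep: float, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    while len(pts) < n:
        p = rng.uniform(low, high)
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
    return np.asarray(pts)


@pytest.fixture(scope="session")
def nuclei_scene():
    """50 nuclei (≥ 8 μm apart) rendered as an unsheared movie at
    1.5 × 1.5 × 3 μm³ voxels, with ground-truth positions and traces."""
    shape = (18, 48, 64)  # z, y, x
    pitch = (1.5, 1.5, 3.0)
    extent = (shape[2] * pitch[0], shape[1] * pitch[1], shape[0] * pitch[2])
    cfg = PopulationConfig(
        n_cells=50,
        duration=120.0,
        n_latent=10,
        noise_sd=10.0,
        brain_extent=tuple(e - 16 for e in extent),
        seed=4,
    )
    pos = _spaced_positions(
        50, np.full(3, 8.0), np.asarray(extent) - 8.0, min_sep=8.0, seed=4
    )
    truth = generate_population_activity(pos, cfg)
    geom = ShearGeometry(slope_s=0.0, native_pitch=pitch, out_pitch=pitch)
    movie = generate_volume_movie(truth, geom, MovieNoiseModel(), shape=shape, seed=4)
    return truth, movie


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
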