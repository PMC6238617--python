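import dataclasses

import numpy as np
import pytest

from cellpol import (
    CellGeometry,
    NoiseSpec,
    PunctaChannelSpec,
    SceneSpec,
    estimate_cell_center,
    simulate_cell,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scene():
    return SceneSpec()


@pytest.fixture
def quiet_noise():
    return NoiseSpec(gaussian_sd=0.0, shot_noise=False, seed=0)


@pytest.fixture
def polarised_cell(scene):
    """A two-channel polarised cell with full channel overlap."""
    chans = [
        PunctaChannelSpec(
            n_puncta=20, polarisation_offset=2.0, placement_spread=1.0, name="puncta"
        ),
        PunctaChannelSpec(
            n_puncta=20, polarisation_offset=2.0, placement_spread=1.0, name="puncta_2"
        ),
    ]
    return simulate_cell(scene, chans, NoiseSpec(seed=7), overlap_fraction=1.0)


def true_geometry(scene: SceneSpec) -> CellGeometry:
    return CellGeometry(
        center=scene.cell_center, radius=scene.cell_radius, source="manual_circle"
    )


def auto_geometry(image, scene: SceneSpec) -> CellGeometry:
    """Nucleus-derived centre with the known cell radius."""
    geom = estimate_cell_center(image.channel("nucleus"), pixel_size=image.pixel_size)
    return dataclasses.replace(geom, radius=scene.cell_radius)
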