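"""Synthetic single-cell image generator with known ground truth.

Cells are modelled as a circular disk containing a nucleus channel
(filled disk) and one or more puncta channels.  Each punctum is an
isotropic Gaussian spot; spot centres are drawn from an isotropic
Gaussian whose centre sits at the cell centre displaced by a planted
polarisation offset, rejection-sampled to stay inside the cell disk.
Displacement zero produces a uniform, cage-like pattern; a positive
displacement produces a collapsed, polarised pattern.

Channel overlap for colocalisation experiments is controlled by reusing
a fraction of spot centres between the first two puncta channels; the
reused fraction is recorded in the ground truth.

Intensities stay floating point throughout; quantisation to uint16
happens only at TIFF export (see :mod:`cellpol.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .image_ops import MultiChannelImage

__all__ = [
    "SceneSpec",
    "PunctaChannelSpec",
    "NoiseSpec",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_cell",
    "simulate_population",
    "DEFAULT_PIXEL_SIZE_UM",
]

# Stand-in sampling for a 63×/1.4 NA confocal; no acquisition pixel size
# is published for the source data, so this default is an artifact choice.
DEFAULT_PIXEL_SIZE_UM = 0.08

_MAX_REJECTION_DRAWS = 10_000


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and background of one synthetic cell scene.

    ``cell_center`` is (x, y) in pixels; radii are in μm.
    """

    image_shape: tuple[int, int] = (112, 112)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    cell_center: tuple[float, float] = (56.0, 56.0)
    cell_radius: float = 3.5
    nucleus_radius: float = 1.5
    background_level: float = 2.0
    nucleus_amplitude: float = 500.0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise SimulationError("pixel_size must be > 0")
        if not (0 < self.nucleus_radius < self.cell_radius):
            raise SimulationError("require 0 < nucleus_radius < cell_radius")
        if self.background_level < 0:
            raise SimulationError("background_level must be ≥ 0")
        r_px = self.cell_radius / self.pixel_size
        cx, cy = self.cell_center
        h, w = self.image_shape
        if not (r_px <= cx <= w - 1 - r_px and r_px <= cy <= h - 1 - r_px):
            raise SimulationError(
                f"cell (centre {self.cell_center}, radius {r_px:.1f} px) does "
                f"not fit inside a {h}×{w} image"
            )

    @property
    def cell_radius_px(self) -> float:
        return self.cell_radius / self.pixel_size


@dataclass(frozen=True)
class PunctaChannelSpec:
    """One puncta channel: spot count, size, brightness and polarisation.

    ``polarisation_offset`` displaces the spot-distribution centre from
    the cell centre along ``polarisation_angle``; 0 gives a uniform,
    cage-like pattern.  ``placement_spread`` is the SD of spot positions
    about that centre.  ``min_separation`` > 0 enforces well-separated
    puncta (useful for cluster-count ground truth).  All lengths in μm.
    """

    n_puncta: int
    puncta_sigma: float = 0.15
    amplitude: float = 500.0
    polarisation_offset: float = 0.0
    polarisation_angle: float = 0.0
    placement_spread: float = 2.0
    min_separation: float = 0.0
    name: str = "puncta"

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise SimulationError("n_puncta must be ≥ 0")
        if not self.puncta_sigma > 0:
            raise SimulationError("puncta_sigma must be > 0")
        if self.polarisation_offset < 0:
            raise SimulationError("polarisation_offset must be ≥ 0")
        if self.placement_spread < 0 or self.min_separation < 0:
            raise SimulationError("spread/separation must be ≥ 0")

    def validate_against(self, scene: SceneSpec) -> None:
        if self.polarisation_offset + self.placement_spread > scene.cell_radius:
            raise SimulationError(
                f"channel {self.name!r}: polarisation_offset + placement_spread "
                f"({self.polarisation_offset} + {self.placement_spread} μm) "
                f"exceeds the cell radius ({scene.cell_radius} μm)"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: optional shot noise, then additive Gaussian read noise."""

    gaussian_sd: float = 1.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise SimulationError("gaussian_sd must be ≥ 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted values recorded alongside each simulated cell."""

    true_center: tuple[float, float]  # (x, y) px
    true_centroid_per_channel: dict[str, tuple[float, float]]
    true_asymmetry: float  # μm, planted offset of the first puncta channel
    true_cluster_count: int
    true_overlap_fraction: float
    spot_centers: dict[str, np.ndarray] = field(compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_asymmetry < 0:
            raise SimulationError("true_asymmetry must be ≥ 0")
        if not (0.0 <= self.true_overlap_fraction <= 1.0):
            raise SimulationError("true_overlap_fraction must lie in [0, 1]")


def _draw_spot_centers(
    spec: PunctaChannelSpec,
    scene: SceneSpec,
    rng: np.random.Generator,
    reused: np.ndarray | None = None,
) -> np.ndarray:
    """Rejection-sample spot centres (x, y, px) inside the cell disk."""
    px = scene.pixel_size
    cx, cy = scene.cell_center
    mu = np.array(
        [
            cx + spec.polarisation_offset * math.cos(spec.polarisation_angle) / px,
            cy + spec.polarisation_offset * math.sin(spec.polarisation_angle) / px,
        ]
    )
    spread_px = spec.placement_spread / px
    r_px = scene.cell_radius_px
    min_sep_px = spec.min_separation / px

    centers: list[np.ndarray] = [] if reused is None else [c for c in reused]
    n_new = spec.n_puncta - len(centers)
    for _ in range(n_new):
        for _attempt in range(_MAX_REJECTION_DRAWS):
            pt = rng.normal(mu, spread_px, size=2)
            if (pt[0] - cx) ** 2 + (pt[1] - cy) ** 2 > r_px**2:
                continue
            if min_sep_px > 0 and any(
                np.hypot(*(pt - c)) < min_sep_px for c in centers
            ):
                continue
            centers.append(pt)
            break
        else:
            raise SimulationError(
                f"channel {spec.name!r}: could not place a punctum inside the "
                f"cell disk after {_MAX_REJECTION_DRAWS} draws"
            )
    return np.array(centers).reshape(-1, 2)


def _render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    """Sum of isotropic Gaussian spots; each rendered in a ±6σ window."""
    img = np.zeros(shape, dtype=float)
    half = int(math.ceil(6 * sigma_px))
    h, w = shape
    for x0, y0 in centers:
        x_lo, x_hi = max(0, int(x0) - half), min(w, int(x0) + half + 1)
        y_lo, y_hi = max(0, int(y0) - half), min(h, int(y0) + half + 1)
        ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        img[y_lo:y_hi, x_lo:x_hi] += amplitude * np.exp(
            -((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * sigma_px**2)
        )
    return img


def _render_nucleus(scene: SceneSpec) -> np.ndarray:
    h, w = scene.image_shape
    ys, xs = np.mgrid[0:h, 0:w]
    cx, cy = scene.cell_center
    r_px = scene.nucleus_radius / scene.pixel_size
    disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= r_px**2
    return scene.nucleus_amplitude * disk.astype(float)


def simulate_cell(
    scene: SceneSpec,
    channels: Sequence[PunctaChannelSpec],
    noise: NoiseSpec,
    *,
    overlap_fraction: float = 0.0,
) -> tuple[MultiChannelImage, GroundTruth]:
    """Simulate one cell: nucleus channel plus the given puncta channels.

    Channel 0 of the output is always the nucleus (a filled disk); the
    puncta channels follow in order.  ``overlap_fraction`` of the second
    puncta channel's spot centres are reused from the first (requires
    ≥ 2 puncta channels when > 0).  Identical specs and seed give
    identical pixel arrays.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise SimulationError("overlap_fraction must lie in [0, 1]")
    if overlap_fraction > 0 and len(channels) < 2:
        raise SimulationError("overlap_fraction needs at least two puncta channels")
    for spec in channels:
        spec.validate_against(scene)

    rng = np.random.default_rng(noise.seed)
    px = scene.pixel_size

    planes = [_render_nucleus(scene)]
    names = ["nucleus"]
    centers_per_channel: dict[str, np.ndarray] = {}
    centroids: dict[str, tuple[float, float]] = {}

    puncta_names: list[str] = []
    for i, spec in enumerate(channels):
        reused = None
        if i == 1 and overlap_fraction > 0:
            first = centers_per_channel[puncta_names[0]]
            n_shared = min(int(round(overlap_fraction * spec.n_puncta)), len(first))
            reused = first[:n_shared]
        centers = _draw_spot_centers(spec, scene, rng, reused=reused)
        name = _unique_name(names, spec.name, i + 1)
        names.append(name)
        puncta_names.append(name)
        centers_per_channel[name] = centers
        if len(centers):
            centroids[name] = (float(centers[:, 0].mean()), float(centers[:, 1].mean()))
        planes.append(
            _render_spots(scene.image_shape, centers, spec.puncta_sigma / px, spec.amplitude)
        )

    stack = np.stack(planes) + scene.background_level
    if noise.shot_noise:
        stack = rng.poisson(stack).astype(float)
    if noise.gaussian_sd > 0:
        stack = stack + rng.normal(0.0, noise.gaussian_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, None)

    image = MultiChannelImage(
        channels=stack, pixel_size=px, channel_names=tuple(names)
    )
    first_spec = channels[0] if channels else None
    truth = GroundTruth(
        true_center=scene.cell_center,
        true_centroid_per_channel=centroids,
        true_asymmetry=first_spec.polarisation_offset if first_spec else 0.0,
        true_cluster_count=first_spec.n_puncta if first_spec else 0,
        true_overlap_fraction=overlap_fraction,
        spot_centers=centers_per_channel,
    )
    return image, truth


def _unique_name(existing: list[str], base: str, index: int) -> str:
    return base if base not in existing else f"{base}_{index}"


@dataclass
class SyntheticDataset:
    """A simulated population: images, ground truths and their table."""

    cells: list[tuple[MultiChannelImage, GroundTruth]]
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.cells)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def simulate_population(
    n_cells: int,
    scene: SceneSpec,
    channels: Sequence[PunctaChannelSpec],
    noise: NoiseSpec,
    *,
    vary: dict[str, Sequence[Any]] | None = None,
    overlap_fraction: float = 0.0,
    master_seed: int | None = None,
) -> SyntheticDataset:
    """Simulate ``n_cells`` independent scenes with per-cell derived seeds.

    ``vary`` maps a parameter name to a list of levels assigned
    cyclically across cells (cell ``i`` gets level ``i % len(levels)``),
    so a two-level list splits an even population exactly in half.
    Supported keys: any :class:`PunctaChannelSpec` field (applied to the
    first puncta channel) and ``"overlap_fraction"``.  A master seed
    deterministically derives one seed per cell.
    """
    if n_cells < 1:
        raise SimulationError("n_cells must be ≥ 1")
    if master_seed is None:
        master_seed = noise.seed
    vary = dict(vary or {})
    for key, levels in vary.items():
        if len(levels) == 0:
            raise SimulationError(f"vary[{key!r}] has no levels")

    child_seeds = [
        int(s.generate_state(1)[0])
        for s in np.random.SeedSequence(master_seed).spawn(n_cells)
    ]

    cells: list[tuple[MultiChannelImage, GroundTruth]] = []
    rows = []
    for i in range(n_cells):
        cell_channels = list(channels)
        cell_overlap = overlap_fraction
        assigned: dict[str, Any] = {}
        for key, levels in vary.items():
            value = levels[i % len(levels)]
            assigned[key] = value
            if key == "overlap_fraction":
                cell_overlap = value
            else:
                if not cell_channels:
                    raise SimulationError(f"vary[{key!r}] requires a puncta channel")
                cell_channels[0] = replace(cell_channels[0], **{key: value})
        cell_noise = replace(noise, seed=child_seeds[i])
        image, truth = simulate_cell(
            scene, cell_channels, cell_noise, overlap_fraction=cell_overlap
        )
        cells.append((image, truth))
        row = {
            "cell_id": i,
            "seed": child_seeds[i],
            "true_center_x": truth.true_center[0],
            "true_center_y": truth.true_center[1],
            "true_asymmetry_um": truth.true_asymmetry,
            "true_cluster_count": truth.true_cluster_count,
            "true_overlap_fraction": truth.true_overlap_fraction,
        }
        row.update({f"vary_{k}": v for k, v in assigned.items()})
        rows.append(row)
    return SyntheticDataset(cells=cells, table=pd.DataFrame(rows))
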