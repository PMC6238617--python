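"""Per-cell polarity statistics.

Asymmetry is the Euclidean distance (μm) between the intensity-weighted
centroid of a compartment channel (computed after local background
subtraction) and the cell centre.  The cluster half-width is the
intensity-weighted standard deviation of labelled cluster pixel
positions, computed separately in x and y and then averaged.

Undefined metrics (e.g. half-width with no clusters) are reported as
NaN, never as zero — zero is a meaningful value for these statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .image_ops import (
    DEFAULT_BACKGROUND_RADIUS_UM,
    DEFAULT_BAND,
    FilterBand,
    ImageOpsError,
    LabelMap,
    MultiChannelImage,
    area_coverage,
    bandpass,
    circular_mask,
    label_clusters,
    max_project,
    otsu_threshold,
    subtract_local_background,
)

__all__ = [
    "CellGeometry",
    "PolarityMetrics",
    "estimate_cell_center",
    "intensity_centroid",
    "asymmetry",
    "cluster_half_width",
    "spot_stats",
    "compute_polarity_metrics",
    "classify_polarised",
]


class PolarityError(ValueError):
    pass


@dataclass(frozen=True)
class CellGeometry:
    """Cell centre (x, y, pixels) and radius (μm)."""

    center: tuple[float, float]
    radius: float
    source: str = "manual_circle"  # or "nucleus_auto"

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise PolarityError(f"cell radius must be > 0, got {self.radius}")
        if self.source not in ("nucleus_auto", "manual_circle"):
            raise PolarityError(f"unknown geometry source {self.source!r}")

    def radius_px(self, pixel_size: float) -> float:
        return self.radius / pixel_size


@dataclass(frozen=True)
class PolarityMetrics:
    cluster_count: int
    asymmetry: float  # μm; NaN when undefined
    half_width: float  # μm; NaN when undefined
    area_coverage: float
    mean_spot_intensity: float  # NaN when no clusters
    mean_spot_area: float  # μm²; NaN when no clusters
    params: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.cluster_count < 0:
            raise PolarityError("cluster_count must be ≥ 0")
        for name in ("asymmetry", "half_width"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise PolarityError(f"{name} must be ≥ 0 or NaN, got {v}")
        if not (0.0 <= self.area_coverage <= 1.0):
            raise PolarityError("area_coverage must lie in [0, 1]")


def estimate_cell_center(
    nucleus: np.ndarray | None = None,
    *,
    manual: tuple[float, float, float] | None = None,
    pixel_size: float | None = None,
) -> CellGeometry:
    """Determine the cell centre and radius.

    In auto mode the nucleus channel is Otsu-thresholded and the
    unweighted centroid of the mask is returned together with the radius
    of the equal-area circle.  In manual mode the supplied circle
    ``(x, y, radius_μm)`` is echoed with ``source="manual_circle"``.
    """
    if manual is not None:
        x, y, radius = manual
        return CellGeometry(center=(float(x), float(y)), radius=float(radius))
    if nucleus is None:
        raise PolarityError("provide either a nucleus channel or a manual circle")
    if pixel_size is None or not pixel_size > 0:
        raise PolarityError("auto mode requires a positive pixel_size")
    nucleus = np.asarray(nucleus, dtype=float)
    if nucleus.min() == nucleus.max():
        raise PolarityError(
            "nucleus channel is constant; supply a manual circle instead"
        )
    threshold = otsu_threshold(nucleus)
    mask = nucleus > threshold
    if not mask.any():
        raise PolarityError(
            "empty nucleus mask after thresholding; supply a manual circle"
        )
    ys, xs = np.nonzero(mask)
    radius_um = math.sqrt(mask.sum() / math.pi) * pixel_size
    return CellGeometry(
        center=(float(xs.mean()), float(ys.mean())),
        radius=radius_um,
        source="nucleus_auto",
    )


def intensity_centroid(
    img: np.ndarray,
    pixel_size: float,
    *,
    background_radius: float = DEFAULT_BACKGROUND_RADIUS_UM,
    mask: np.ndarray | None = None,
    subtract_background: bool = True,
) -> tuple[float, float]:
    """Mean pixel position weighted by pixel intensity, as (x, y) px.

    Local background (morphological opening at ``background_radius``,
    default 2.6 μm) is subtracted first; pixels outside ``mask`` carry
    zero weight.
    """
    img = np.asarray(img, dtype=float)
    if subtract_background:
        weights = subtract_local_background(img, background_radius, pixel_size)
    else:
        weights = img.copy()
    if mask is not None:
        weights = np.where(np.asarray(mask, dtype=bool), weights, 0.0)
        raw_total = img[np.asarray(mask, dtype=bool)].sum()
    else:
        raw_total = img.sum()
    total = weights.sum()
    if total <= 0:
        if raw_total <= 0:
            raise PolarityError("empty channel: no intensity to weight")
        raise PolarityError(
            "all-background channel: no intensity remains after background "
            "subtraction"
        )
    ys, xs = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return (
        float((xs * weights).sum() / total),
        float((ys * weights).sum() / total),
    )


def asymmetry(
    centroid: tuple[float, float],
    geometry: CellGeometry,
    pixel_size: float,
    *,
    normalise: bool = False,
) -> float:
    """Euclidean distance (μm) between the centroid and the cell centre.

    With ``normalise=True`` the distance is divided by the cell radius.
    """
    dx = centroid[0] - geometry.center[0]
    dy = centroid[1] - geometry.center[1]
    dist = math.hypot(dx, dy) * pixel_size
    if normalise:
        dist /= geometry.radius
    return dist


def cluster_half_width(
    labels: LabelMap, img: np.ndarray, pixel_size: float
) -> float:
    """Intensity-weighted SD of cluster pixel positions, x/y-averaged, μm.

    Only labelled (cluster) pixels contribute.  Returns NaN when there
    are no clusters or no positive intensity on them.
    """
    img = np.asarray(img, dtype=float)
    mask = labels.labels > 0
    if not mask.any():
        return float("nan")
    w = img[mask]
    total = w.sum()
    if total <= 0:
        return float("nan")
    ys, xs = np.nonzero(mask)
    xbar = (xs * w).sum() / total
    ybar = (ys * w).sum() / total
    sd_x = math.sqrt(((xs - xbar) ** 2 * w).sum() / total)
    sd_y = math.sqrt(((ys - ybar) ** 2 * w).sum() / total)
    return 0.5 * (sd_x + sd_y) * pixel_size


def spot_stats(
    labels: LabelMap, img: np.ndarray, pixel_size: float
) -> tuple[float, float]:
    """(mean spot intensity, mean spot area in μm²) over clusters.

    The first entry averages, over clusters, each cluster's mean pixel
    intensity; the second averages the cluster areas.  Both are NaN when
    there are no clusters.
    """
    img = np.asarray(img, dtype=float)
    if labels.n_clusters == 0:
        return float("nan"), float("nan")
    lab = labels.labels
    flat = lab.ravel()
    sums = np.bincount(flat, weights=img.ravel(), minlength=labels.n_clusters + 1)
    areas = np.bincount(flat, minlength=labels.n_clusters + 1)
    means = sums[1:] / areas[1:]
    mean_area_um2 = areas[1:].mean() * pixel_size**2
    return float(means.mean()), float(mean_area_um2)


def compute_polarity_metrics(
    image: MultiChannelImage,
    channel: str,
    geometry: CellGeometry,
    *,
    band: FilterBand = DEFAULT_BAND,
    background_radius: float = DEFAULT_BACKGROUND_RADIUS_UM,
    otsu_bins: int = 256,
    min_cluster_area: int = 4,
    connectivity: int = 8,
    restrict_to_cell: bool = True,
) -> PolarityMetrics:
    """Run the full per-channel polarity chain on one cell.

    Segmentation path: max-project → bandpass → Otsu → connected
    components → cluster count, half-width, spot statistics and area
    coverage.  Centroid path (independent of segmentation): local
    background subtraction → intensity-weighted centroid → asymmetry.
    """
    stage = "projection"
    try:
        flat = max_project(image)
        chan = flat.channel(channel)
        px = flat.pixel_size

        cell_mask = None
        if restrict_to_cell:
            cell_mask = circular_mask(
                chan.shape, geometry.center, geometry.radius_px(px)
            )

        stage = "bandpass"
        filtered = bandpass(chan, band, px)

        stage = "otsu"
        threshold = otsu_threshold(filtered, n_bins=otsu_bins)

        stage = "labeling"
        seg = filtered > threshold
        if cell_mask is not None:
            seg &= cell_mask
        labels = label_clusters(seg, min_area=min_cluster_area, connectivity=connectivity)

        stage = "cluster metrics"
        half_width = cluster_half_width(labels, filtered, px)
        mean_intensity, mean_area = spot_stats(labels, filtered, px)
        coverage = area_coverage(filtered, threshold, mask=cell_mask)

        stage = "centroid"
        centroid = intensity_centroid(
            chan, px, background_radius=background_radius, mask=cell_mask
        )
        asym = asymmetry(centroid, geometry, px)
    except (ImageOpsError, PolarityError) as exc:
        raise PolarityError(f"polarity stage {stage!r} failed: {exc}") from exc

    params = {
        "channel": channel,
        "band_low_um": band.low_scale,
        "band_high_um": band.high_scale,
        "background_radius_um": background_radius,
        "otsu_bins": otsu_bins,
        "otsu_threshold": threshold,
        "min_cluster_area_px": min_cluster_area,
        "connectivity": connectivity,
        "geometry_source": geometry.source,
        "restrict_to_cell": restrict_to_cell,
    }
    return PolarityMetrics(
        cluster_count=labels.n_clusters,
        asymmetry=asym,
        half_width=half_width,
        area_coverage=coverage,
        mean_spot_intensity=mean_intensity,
        mean_spot_area=mean_area,
        params=params,
    )


def classify_polarised(metrics: PolarityMetrics, asymmetry_threshold: float) -> bool:
    """Flag a cell as polarised iff asymmetry strictly exceeds the threshold.

    The threshold must be supplied or calibrated by the caller; no
    biological default is asserted.
    """
    if math.isnan(metrics.asymmetry):
        raise PolarityError("asymmetry is undefined; cannot classify")
    return metrics.asymmetry > asymmetry_threshold
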