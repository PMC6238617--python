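"""Costes-thresholded Pearson/Manders colocalisation between two channels.

The automatic threshold pair is found by fitting an orthogonal (total
least squares) regression ``b = slope·a + intercept`` over the analysed
pixels, then sweeping a candidate threshold on channel A downward from
its maximum with the channel-B threshold slaved to the regression line,
and stopping at the highest threshold where the Pearson correlation of
the jointly-below-threshold pixels first drops to ≤ 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .image_ops import MultiChannelImage, circular_mask, max_project
from .polarity import CellGeometry

__all__ = [
    "ColocError",
    "ColocalisationReport",
    "crop_to_cell",
    "pearson",
    "costes_thresholds",
    "manders",
    "colocalise_cell",
]


class ColocError(ValueError):
    pass


@dataclass(frozen=True)
class ColocalisationReport:
    pearson_r: float  # over all analysed pixels
    pearson_r_above_threshold: float  # over jointly above-threshold pixels
    costes_threshold_a: float
    costes_threshold_b: float
    manders_m1: float
    manders_m2: float
    n_pixels_analysed: int
    regression_slope: float
    regression_intercept: float
    flags: tuple[str, ...] = ()
    params: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.n_pixels_analysed <= 0:
            raise ColocError("n_pixels_analysed must be > 0")
        if not math.isnan(self.pearson_r) and abs(self.pearson_r) > 1 + 1e-12:
            raise ColocError("|pearson_r| must be ≤ 1")
        for name in ("manders_m1", "manders_m2"):
            v = getattr(self, name)
            if not math.isnan(v) and not (-1e-12 <= v <= 1 + 1e-12):
                raise ColocError(f"{name} must lie in [0, 1]")


def crop_to_cell(
    image: MultiChannelImage, geometry: CellGeometry, padding: float = 0.0
) -> tuple[MultiChannelImage, CellGeometry]:
    """Crop to the cell circle plus padding (μm), clamped to the frame.

    Returns the crop and the geometry re-expressed in crop coordinates.
    """
    px = image.pixel_size
    cx, cy = geometry.center
    extent = (geometry.radius + padding) / px
    h, w = image.shape_yx
    x0 = max(0, int(math.floor(cx - extent)))
    x1 = min(w, int(math.ceil(cx + extent)) + 1)
    y0 = max(0, int(math.floor(cy - extent)))
    y1 = min(h, int(math.ceil(cy + extent)) + 1)
    if (x1 - x0) < 4 or (y1 - y0) < 4:
        raise ColocError(f"degenerate crop ({y1 - y0}×{x1 - x0} px)")
    cropped = MultiChannelImage(
        channels=image.channels[..., y0:y1, x0:x1],
        pixel_size=px,
        channel_names=image.channel_names,
    )
    new_geometry = CellGeometry(
        center=(cx - x0, cy - y0), radius=geometry.radius, source=geometry.source
    )
    return cropped, new_geometry


def _masked_pair(
    chan_a: np.ndarray, chan_b: np.ndarray, mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(chan_a, dtype=float)
    b = np.asarray(chan_b, dtype=float)
    if a.shape != b.shape:
        raise ColocError("channel shapes differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ColocError("mask shape must match channel shape")
        return a[mask], b[mask]
    return a.ravel(), b.ravel()


def pearson(
    chan_a: np.ndarray, chan_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Sample Pearson correlation of paired intensities over the mask.

    Returns NaN when either channel is constant on the mask (undefined).
    """
    a, b = _masked_pair(chan_a, chan_b, mask)
    if a.size < 2:
        raise ColocError("Pearson requires ≥ 2 masked pixels")
    return _pearson_of(a, b)


def _pearson_of(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    va = (da * da).sum()
    vb = (db * db).sum()
    if va == 0.0 or vb == 0.0:
        return float("nan")
    return float((da * db).sum() / math.sqrt(va * vb))


def _orthogonal_fit(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line b = slope·a + intercept."""
    sxx = a.var()
    syy = b.var()
    sxy = ((a - a.mean()) * (b - b.mean())).mean()
    if sxy == 0.0:
        raise ColocError("channels uncorrelated; Costes regression undefined")
    slope = (syy - sxx + math.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    intercept = b.mean() - slope * a.mean()
    return slope, intercept


def _ols_fit(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    sxx = a.var()
    if sxx == 0.0:
        raise ColocError("channel A constant; regression undefined")
    slope = ((a - a.mean()) * (b - b.mean())).mean() / sxx
    intercept = b.mean() - slope * a.mean()
    return slope, intercept


def costes_thresholds(
    chan_a: np.ndarray,
    chan_b: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    regression: str = "orthogonal",
    max_candidates: int = 512,
) -> tuple[float, float, float, float, tuple[str, ...]]:
    """Costes automatic threshold pair.

    Returns ``(t_a, t_b, slope, intercept, flags)``.  Candidate levels
    are the sorted unique intensities of channel A, thinned to at most
    ``max_candidates`` by evenly spaced rank (scale-free and
    deterministic).  If the below-threshold correlation never drops to
    ≤ 0 the minimum intensity is returned with a ``"no_zero_crossing"``
    flag.
    """
    a, b = _masked_pair(chan_a, chan_b, mask)
    if a.size < 2:
        raise ColocError("Costes thresholding requires ≥ 2 masked pixels")
    fit = {"orthogonal": _orthogonal_fit, "ols": _ols_fit}.get(regression)
    if fit is None:
        raise ColocError(f"unknown regression {regression!r}")
    slope, intercept = fit(a, b)
    if slope <= 0:
        raise ColocError("channels anti-correlated; Costes threshold undefined")

    levels = np.unique(a)[::-1]  # descending
    if levels.size > max_candidates:
        idx = np.unique(
            np.round(np.linspace(0, levels.size - 1, max_candidates)).astype(int)
        )
        levels = levels[idx]
    for t_a in levels:
        t_b = slope * t_a + intercept
        below = (a < t_a) & (b < t_b)
        if below.sum() < 2:
            continue
        r = _pearson_of(a[below], b[below])
        if not math.isnan(r) and r <= 0.0:
            return float(t_a), float(t_b), slope, intercept, ()
    t_a = float(a.min())
    return t_a, slope * t_a + intercept, slope, intercept, ("no_zero_crossing",)


def manders(
    chan_a: np.ndarray,
    chan_b: np.ndarray,
    t_a: float,
    t_b: float,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Manders coefficients at the given thresholds.

    ``M1`` is the fraction of channel-A intensity found where channel B
    exceeds its threshold; ``M2`` is the symmetric quantity.  A zero
    denominator yields NaN.
    """
    a, b = _masked_pair(chan_a, chan_b, mask)
    sum_a = a.sum()
    sum_b = b.sum()
    m1 = float(a[b > t_b].sum() / sum_a) if sum_a > 0 else float("nan")
    m2 = float(b[a > t_a].sum() / sum_b) if sum_b > 0 else float("nan")
    return m1, m2


def colocalise_cell(
    image: MultiChannelImage,
    geometry: CellGeometry,
    chan_a_name: str,
    chan_b_name: str,
    *,
    padding: float = 0.0,
    mask_shape: str = "circle",
    regression: str = "orthogonal",
    max_candidates: int = 512,
) -> ColocalisationReport:
    """Crop to the cell, find Costes thresholds, report Pearson and Manders.

    The analysed pixel set is the cell circle by default
    (``mask_shape="rectangle"`` selects the full crop).  Pearson is
    reported both over all analysed pixels and over the jointly
    above-threshold subset.
    """
    cropped, geom = crop_to_cell(image, geometry, padding=padding)
    flat = max_project(cropped)
    a = flat.channel(chan_a_name)
    b = flat.channel(chan_b_name)
    if mask_shape == "circle":
        mask = circular_mask(a.shape, geom.center, geom.radius_px(flat.pixel_size))
    elif mask_shape == "rectangle":
        mask = np.ones(a.shape, dtype=bool)
    else:
        raise ColocError(f"unknown mask_shape {mask_shape!r}")

    try:
        t_a, t_b, slope, intercept, flags = costes_thresholds(
            a, b, mask, regression=regression, max_candidates=max_candidates
        )
    except ColocError:
        # No positive inter-channel association: no pixel qualifies as
        # colocalised.  Report thresholds at the channel maxima (M1 = M2
        # = 0) with a flag rather than failing the cell.
        t_a = float(a[mask].max())
        t_b = float(b[mask].max())
        slope = float("nan")
        intercept = float("nan")
        flags = ("anti_correlated",)
    r_all = pearson(a, b, mask)
    above = mask & (a > t_a) & (b > t_b)
    if above.sum() >= 2:
        r_above = pearson(a, b, above)
    else:
        r_above = float("nan")
        flags = flags + ("too_few_above_threshold_pixels",)
    m1, m2 = manders(a, b, t_a, t_b, mask)

    params = {
        "chan_a": chan_a_name,
        "chan_b": chan_b_name,
        "padding_um": padding,
        "mask_shape": mask_shape,
        "regression": regression,
        "max_candidates": max_candidates,
        "manders_thresholds": "costes",
    }
    return ColocalisationReport(
        pearson_r=r_all,
        pearson_r_above_threshold=r_above,
        costes_threshold_a=t_a,
        costes_threshold_b=t_b,
        manders_m1=m1,
        manders_m2=m2,
        n_pixels_analysed=int(mask.sum()),
        regression_slope=slope,
        regression_intercept=intercept,
        flags=flags,
        params=params,
    )
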