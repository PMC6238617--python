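"""Core image operations of the per-cell analysis chain.

All physical parameters are expressed in micrometres and converted to
pixels through the image's ``pixel_size`` (μm/pixel).  The coordinate
convention throughout the package is x = column, y = row, origin at the
top-left corner, pixel centres at integer coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import measure, morphology

__all__ = [
    "MultiChannelImage",
    "FilterBand",
    "LabelMap",
    "max_project",
    "bandpass",
    "subtract_local_background",
    "otsu_threshold",
    "label_clusters",
    "area_coverage",
]


class ImageOpsError(ValueError):
    """Raised when an image operation's preconditions are violated."""


@dataclass(frozen=True)
class MultiChannelImage:
    """A multi-channel (optionally multi-z) single-cell image crop.

    Parameters
    ----------
    channels
        Array of shape ``(C, H, W)`` for 2D images or ``(C, Z, H, W)``
        for z-stacks.  Intensities must be finite and non-negative.
    pixel_size
        Physical pixel size in μm/pixel.
    channel_names
        One label per channel.
    """

    channels: np.ndarray
    pixel_size: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=float)
        if arr.ndim not in (3, 4):
            raise ImageOpsError(
                f"channels must have shape (C, H, W) or (C, Z, H, W); got ndim={arr.ndim}"
            )
        if not np.isfinite(arr).all():
            raise ImageOpsError("image intensities must be finite")
        if (arr < 0).any():
            raise ImageOpsError("image intensities must be non-negative")
        if not self.pixel_size > 0:
            raise ImageOpsError(f"pixel_size must be > 0, got {self.pixel_size}")
        names = tuple(self.channel_names)
        if not names:
            names = tuple(f"channel_{i}" for i in range(arr.shape[0]))
        if len(names) != arr.shape[0]:
            raise ImageOpsError(
                f"{len(names)} channel names for {arr.shape[0]} channels"
            )
        object.__setattr__(self, "channels", arr)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def has_z(self) -> bool:
        return self.channels.ndim == 4

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.channels.shape[-2], self.channels.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's pixel grid by name (2D, or (Z, H, W))."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ImageOpsError(
                f"unknown channel {name!r}; available: {list(self.channel_names)}"
            ) from None
        return self.channels[idx]


@dataclass(frozen=True)
class FilterBand:
    """Spatial-scale band for the bandpass filter, in μm."""

    low_scale: float
    high_scale: float

    def __post_init__(self) -> None:
        if not (0 < self.low_scale < self.high_scale):
            raise ImageOpsError(
                f"require 0 < low_scale < high_scale; got "
                f"({self.low_scale}, {self.high_scale})"
            )


# Scales published for the analysis this package reimplements.
DEFAULT_BAND = FilterBand(low_scale=0.13, high_scale=0.9)
DEFAULT_BACKGROUND_RADIUS_UM = 2.6


@dataclass(frozen=True)
class LabelMap:
    """Integer-labelled segmentation; 0 is background, clusters are 1..n."""

    labels: np.ndarray
    n_clusters: int
    min_area: int = 4
    connectivity: int = 8

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        present = np.unique(lab)
        present = present[present > 0]
        if len(present) != self.n_clusters or (
            len(present) and (present != np.arange(1, self.n_clusters + 1)).any()
        ):
            raise ImageOpsError("labels must be consecutive 1..n_clusters")
        object.__setattr__(self, "labels", lab)

    def cluster_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def max_project(image: MultiChannelImage) -> MultiChannelImage:
    """Maximum-intensity projection of a z-stack along z.

    A 2D image is returned unchanged (identity on single-slice input).
    """
    if not image.has_z:
        return image
    if image.channels.shape[1] < 1:
        raise ImageOpsError("empty z-stack")
    return MultiChannelImage(
        channels=image.channels.max(axis=1),
        pixel_size=image.pixel_size,
        channel_names=image.channel_names,
    )


def bandpass(
    img: np.ndarray,
    band: FilterBand,
    pixel_size: float,
    *,
    clip: bool = True,
    sigma_divisor: float = 2.0,
    mode: str = "reflect",
) -> np.ndarray:
    """Difference-of-Gaussians bandpass at physical scales.

    The band scales (μm) map to Gaussian sigmas in pixels as
    ``sigma = scale / (sigma_divisor * pixel_size)``; the response is
    ``G(sigma_low) - G(sigma_high)``.  ``sigma_divisor=2.0`` reads the
    scale as a full width of ~2σ; ``2.355`` reads it as a FWHM.

    The image minimum (an exact array element) is subtracted before
    filtering so a constant image maps to exactly zero — the DoG
    annihilates constants in exact arithmetic, and referencing to an
    element value makes that hold in floating point too.  This leaves
    the response to non-constant images unchanged up to rounding and
    keeps the operator linear pre-clipping.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ImageOpsError("bandpass expects a 2D image")
    sigma_low = band.low_scale / (sigma_divisor * pixel_size)
    sigma_high = band.high_scale / (sigma_divisor * pixel_size)
    if sigma_high >= min(img.shape):
        raise ImageOpsError(
            f"high_scale {band.high_scale} μm exceeds the image extent at "
            f"pixel_size {pixel_size} μm/px"
        )
    centred = img - img.min()
    out = ndi.gaussian_filter(centred, sigma_low, mode=mode) - ndi.gaussian_filter(
        centred, sigma_high, mode=mode
    )
    if clip:
        out = np.clip(out, 0.0, None)
    return out


def subtract_local_background(
    img: np.ndarray,
    radius: float,
    pixel_size: float,
    *,
    method: str = "opening",
) -> np.ndarray:
    """Subtract a locally estimated background and clip at zero.

    The background is the morphological (grey) opening of the image by a
    flat disk of the given physical radius — a rolling-ball-like
    estimate robust to bright puncta.  ``method="median"`` selects a
    local-median background instead.

    If the disk does not fit in the image half-extent a warning is
    emitted and the global minimum is subtracted instead.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ImageOpsError("subtract_local_background expects a 2D image")
    radius_px = radius / pixel_size
    if radius_px < 1.0:
        raise ImageOpsError(
            f"background radius {radius} μm is below one pixel at "
            f"{pixel_size} μm/px"
        )
    if radius_px > min(img.shape) / 2:
        warnings.warn(
            "background radius exceeds the image half-extent; "
            "falling back to global-minimum subtraction",
            stacklevel=2,
        )
        return np.clip(img - img.min(), 0.0, None)
    footprint = morphology.disk(int(round(radius_px)))
    if method == "opening":
        background = morphology.opening(img, footprint)
    elif method == "median":
        background = ndi.median_filter(img, footprint=footprint)
    else:
        raise ImageOpsError(f"unknown background method {method!r}")
    return np.clip(img - background, 0.0, None)


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the bin edge maximising between-class variance.

    The histogram spans the image's min–max range with ``n_bins`` bins.
    The returned value is the upper edge of the last background bin, so
    foreground is ``img > threshold``.  Ties are broken toward the lower
    threshold.  Raises on a constant image (threshold undefined).
    """
    values = np.asarray(img, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise ImageOpsError("Otsu threshold undefined for a constant image")
    hist, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    hist = hist.astype(float)
    # exact per-bin intensity sums, so class means are exact rather than
    # bin-centre approximations (keeps equality with an exhaustive search)
    value_sums, _ = np.histogram(
        values, bins=n_bins, range=(vmin, vmax), weights=values
    )
    total = hist.sum()
    w0 = np.cumsum(hist)
    w1 = total - w0
    cum_mean = np.cumsum(value_sums)
    grand_mean = cum_mean[-1]
    # between-class variance for a cut after bin k, defined where both
    # classes are non-empty
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand_mean - cum_mean) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = sigma_b[:-1]  # a cut after the last bin leaves class 1 empty
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))  # first max == lower threshold on ties
    return float(edges[k + 1])


def label_clusters(
    mask: np.ndarray, min_area: int = 4, connectivity: int = 8
) -> LabelMap:
    """Label connected components of a binary mask, dropping small ones.

    Components with fewer than ``min_area`` pixels are discarded and the
    survivors renumbered consecutively from 1.  Connectivity is 8 (the
    default; diagonal neighbours connect) or 4.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ImageOpsError("connectivity must be 4 or 8")
    skimage_conn = 2 if connectivity == 8 else 1
    raw = measure.label(mask, connectivity=skimage_conn)
    counts = np.bincount(raw.ravel())
    keep = np.flatnonzero(counts >= min_area)
    keep = keep[keep > 0]
    remap = np.zeros(raw.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return LabelMap(
        labels=remap[raw],
        n_clusters=len(keep),
        min_area=min_area,
        connectivity=connectivity,
    )


def area_coverage(
    img: np.ndarray, threshold: float, mask: np.ndarray | None = None
) -> float:
    """Fraction of (masked) pixels whose intensity exceeds ``threshold``."""
    img = np.asarray(img, dtype=float)
    if not np.isfinite(threshold):
        raise ImageOpsError("threshold must be finite")
    above = img > threshold
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ImageOpsError("mask shape must match image shape")
        if not mask.any():
            raise ImageOpsError("empty mask: area coverage undefined")
        return float(above[mask].mean())
    return float(above.mean())


def circular_mask(
    shape: tuple[int, int], center: tuple[float, float], radius_px: float
) -> np.ndarray:
    """Boolean disk mask; ``center`` is (x, y) in pixels."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
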