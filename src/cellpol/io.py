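"""TIFF and CSV input/output.

Images travel as multi-page TIFF with one page per channel (or per
z-slice and channel).  Pixel size and channel layout are stored as a
JSON payload in the ImageDescription tag, plus standard resolution tags
for interoperability; on read the JSON wins, then the resolution tags,
then an explicit override.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .image_ops import ImageOpsError, MultiChannelImage

__all__ = ["read_image", "write_image"]


class ImageIOError(ValueError):
    pass


def write_image(
    image: MultiChannelImage, path: str | Path, *, quantise: bool = False
) -> Path:
    """Write a multi-page TIFF; one page per channel (and z-slice).

    ``quantise=True`` rounds and clips to the unsigned 16-bit range;
    otherwise the floating-point intensities are written as-is.
    """
    path = Path(path)
    data = image.channels
    if quantise:
        data = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    axes = "CZYX" if image.has_z else "CYX"
    description = json.dumps(
        {
            "pixel_size_um": image.pixel_size,
            "channel_names": list(image.channel_names),
            "axes": axes,
        }
    )
    pixels_per_cm = 1e4 / image.pixel_size
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=description,
        resolution=(pixels_per_cm, pixels_per_cm),
        resolutionunit="CENTIMETER",
    )
    return path


def _pixel_size_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value
    unit_um = {2: 25_400.0, 3: 10_000.0}.get(int(unit))  # inch, cm
    if unit_um is None:
        return None
    return unit_um * den / num


def read_image(
    path: str | Path, pixel_size: float | None = None
) -> MultiChannelImage:
    """Read a single- or multi-page TIFF into a :class:`MultiChannelImage`.

    ``pixel_size`` overrides any metadata value (with a warning when
    both are present).  A file carrying no pixel size and no override is
    an error, as is a 4D array with no axis annotation.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            description = tif.pages[0].description or ""
            tag_px = _pixel_size_from_tags(tif.pages[0])
    except (OSError, tifffile.TiffFileError) as exc:
        raise ImageIOError(f"cannot read TIFF {path}: {exc}") from exc

    meta: dict = {}
    if description:
        try:
            parsed = json.loads(description)
            if isinstance(parsed, dict):
                meta = parsed
        except json.JSONDecodeError:
            pass

    meta_px = meta.get("pixel_size_um", tag_px)
    if pixel_size is not None:
        if meta_px is not None and not np.isclose(meta_px, pixel_size):
            warnings.warn(
                f"{path.name}: overriding metadata pixel size "
                f"{meta_px:g} μm/px with {pixel_size:g} μm/px",
                stacklevel=2,
            )
        resolved_px = pixel_size
    elif meta_px is not None:
        resolved_px = float(meta_px)
    else:
        raise ImageIOError(
            f"{path}: no pixel size in metadata; pass an explicit override"
        )

    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    axes = meta.get("axes")
    if data.ndim == 4 and axes not in ("CZYX",):
        if axes is None:
            raise ImageIOError(
                f"{path}: 4D TIFF with no axis annotation; cannot tell "
                "channels from z-slices"
            )
        raise ImageIOError(f"{path}: unsupported axis order {axes!r}")
    if data.ndim == 3 and axes not in (None, "CYX"):
        raise ImageIOError(f"{path}: unsupported axis order {axes!r}")

    names = tuple(meta.get("channel_names", ()))
    try:
        return MultiChannelImage(
            channels=data, pixel_size=resolved_px, channel_names=names
        )
    except ImageOpsError as exc:
        raise ImageIOError(f"{path}: {exc}") from exc
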