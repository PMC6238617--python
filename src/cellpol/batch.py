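"""Batch orchestration: run the full pipeline over many cell crops.

Each input crop holds one cell.  Per-cell failures are recorded as rows
with a non-empty ``error`` column and never abort the batch; only an
all-cells-failed batch raises.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .coloc import ColocError, colocalise_cell
from .config import RunConfig
from .image_ops import ImageOpsError, MultiChannelImage, max_project
from .io import ImageIOError, read_image
from .polarity import (
    CellGeometry,
    PolarityError,
    compute_polarity_metrics,
    estimate_cell_center,
)
from .synthetic import SyntheticDataset

__all__ = ["run_batch", "write_results", "BatchError"]

logger = logging.getLogger("cellpol.batch")

_CELL_ERRORS = (ImageOpsError, ImageIOError, PolarityError, ColocError)


class BatchError(RuntimeError):
    pass


def _iter_cells(
    inputs: Sequence[str | Path] | SyntheticDataset, config: RunConfig
) -> Iterable[tuple[str, MultiChannelImage | None, str | None]]:
    if isinstance(inputs, SyntheticDataset):
        for i, (image, _truth) in enumerate(inputs.cells):
            yield f"cell_{i:04d}", image, None
        return
    for path in inputs:
        path = Path(path)
        try:
            yield path.stem, read_image(path, pixel_size=config.pixel_size), None
        except _CELL_ERRORS as exc:
            yield path.stem, None, str(exc)


def _geometry_for(image: MultiChannelImage, config: RunConfig) -> CellGeometry:
    flat = max_project(image)
    nucleus_name = config.channel_roles["nucleus"]
    geometry = estimate_cell_center(
        flat.channel(nucleus_name), pixel_size=flat.pixel_size
    )
    if config.cell_radius is not None:
        geometry = CellGeometry(
            center=geometry.center, radius=config.cell_radius, source=geometry.source
        )
    return geometry


def run_batch(
    inputs: Sequence[str | Path] | SyntheticDataset, config: RunConfig
) -> dict[str, pd.DataFrame]:
    """Run polarity and colocalisation over all input cells.

    Returns ``{"polarity": ..., "coloc": ...}`` DataFrames with one row
    per cell per compartment channel (polarity) and one row per cell
    (colocalisation, when both compartments are configured).  Rows are
    sorted by cell id, so the result is independent of input ordering.
    """
    compartments = [
        config.channel_roles[r]
        for r in ("compartment_a", "compartment_b")
        if r in config.channel_roles and config.channel_roles[r]
    ]
    pol_rows: list[dict] = []
    coloc_rows: list[dict] = []
    n_cells = n_failed = 0

    for cell_id, image, load_error in _iter_cells(inputs, config):
        n_cells += 1
        if load_error is not None:
            logger.warning("cell %s: load failed: %s", cell_id, load_error)
            pol_rows.append({"cell_id": cell_id, "error": load_error})
            n_failed += 1
            continue
        try:
            geometry = _geometry_for(image, config)
        except _CELL_ERRORS as exc:
            logger.warning("cell %s: geometry failed: %s", cell_id, exc)
            pol_rows.append({"cell_id": cell_id, "error": f"geometry: {exc}"})
            n_failed += 1
            continue

        cell_ok = False
        for chan in compartments:
            if chan not in image.channel_names:
                continue
            try:
                m = compute_polarity_metrics(
                    image,
                    chan,
                    geometry,
                    band=config.band,
                    background_radius=config.background_radius,
                    otsu_bins=config.otsu_bins,
                    min_cluster_area=config.min_cluster_area,
                    connectivity=config.connectivity,
                )
            except _CELL_ERRORS as exc:
                logger.warning("cell %s/%s: polarity failed: %s", cell_id, chan, exc)
                pol_rows.append(
                    {"cell_id": cell_id, "channel": chan, "error": str(exc)}
                )
                continue
            cell_ok = True
            pol_rows.append(
                {
                    "cell_id": cell_id,
                    "channel": chan,
                    "cluster_count": m.cluster_count,
                    "asymmetry_um": m.asymmetry,
                    "half_width_um": m.half_width,
                    "area_coverage": m.area_coverage,
                    "mean_spot_intensity": m.mean_spot_intensity,
                    "mean_spot_area_um2": m.mean_spot_area,
                    "geometry_source": geometry.source,
                    "cell_radius_um": geometry.radius,
                    "error": "",
                    **{f"param_{k}": v for k, v in m.params.items() if k != "channel"},
                }
            )

        if len(compartments) >= 2 and all(
            c in image.channel_names for c in compartments[:2]
        ):
            try:
                report = colocalise_cell(
                    image,
                    geometry,
                    compartments[0],
                    compartments[1],
                    padding=config.coloc_padding,
                    mask_shape=config.coloc_mask_shape,
                    regression=config.coloc_regression,
                )
                cell_ok = True
                coloc_rows.append(
                    {
                        "cell_id": cell_id,
                        "chan_a": compartments[0],
                        "chan_b": compartments[1],
                        "pearson_r_all": report.pearson_r,
                        "pearson_r_above_threshold": report.pearson_r_above_threshold,
                        "t_a": report.costes_threshold_a,
                        "t_b": report.costes_threshold_b,
                        "manders_m1": report.manders_m1,
                        "manders_m2": report.manders_m2,
                        "n_pixels": report.n_pixels_analysed,
                        "regression_slope": report.regression_slope,
                        "regression_intercept": report.regression_intercept,
                        "flags": ";".join(report.flags),
                        "error": "",
                    }
                )
            except _CELL_ERRORS as exc:
                logger.warning("cell %s: coloc failed: %s", cell_id, exc)
                coloc_rows.append({"cell_id": cell_id, "error": str(exc)})
        if not cell_ok:
            n_failed += 1

    if n_cells == 0:
        raise BatchError("no input cells")
    if n_failed == n_cells:
        raise BatchError(f"all {n_cells} cells failed; see the result rows")

    pol = pd.DataFrame(pol_rows)
    sort_cols = [c for c in ("cell_id", "channel") if c in pol.columns]
    pol = pol.sort_values(sort_cols).reset_index(drop=True)
    coloc = pd.DataFrame(coloc_rows)
    if not coloc.empty:
        coloc = coloc.sort_values("cell_id").reset_index(drop=True)
    return {"polarity": pol, "coloc": coloc}


def write_results(
    results: dict[str, pd.DataFrame], out_dir: str | Path, config: RunConfig
) -> list[Path]:
    """Write result CSVs with a parameter-echo comment header.

    The header carries the tool version and every resolved parameter but
    no timestamp, so identical runs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header_lines = [f"# cellpol {__version__}"]
    for key, value in sorted(config.to_dict().items()):
        header_lines.append(f"# {key}: {value}")
    header = "\n".join(header_lines) + "\n"

    written = []
    for name, df in results.items():
        if df.empty:
            continue
        path = out_dir / f"{name}.csv"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        written.append(path)
    return written
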