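# cellpol

Quantification of intracellular compartment **polarisation** and
**colocalisation** in single-cell fluorescence image crops, plus a
synthetic-cell image simulator with known ground truth.

Given a multi-channel (optionally multi-z) TIFF crop of one cell with a
known pixel size, the pipeline computes per cell:

- **Polarity metrics** — maximum-intensity projection → physical-scale
  difference-of-Gaussians bandpass (default 0.13–0.9 μm) → Otsu
  segmentation → connected-component labelling, yielding the cluster
  count, cluster half-width (intensity-weighted SD of cluster pixel
  positions, x/y-averaged, μm), area coverage and mean spot
  intensity/area; and, independently, local background subtraction
  (morphological opening, default 2.6 μm radius) → intensity-weighted
  centroid → **asymmetry** (distance from the cell centre, μm).
- **Colocalisation** — crop to the cell, Costes automatic thresholding
  (orthogonal regression + descending threshold sweep until the
  below-threshold pixels decorrelate), Pearson correlation and Manders
  M1/M2 coefficients.

The cell centre comes from Otsu-thresholding the nucleus channel (or a
manual circle). The `cellpol.synthetic` module generates circular cells
with diffraction-limited puncta placed uniformly ("cage-like") or
polarised toward one pole, tunable inter-channel overlap, shot and read
noise — the recovery targets used throughout the test suite.

## CLI

```sh
# simulate 20 polarised cells (offset 2 μm) with ground truth
cellpol simulate --cells 20 --offset 2.0 --seed 7 --out simulated/

# per-cell analyses (cell radius in μm overrides the nucleus-derived one)
cellpol polarity simulated/cell_0000.tif --cell-radius 3.5
cellpol coloc simulated/cell_0000.tif --cell-radius 3.5

# batch over many crops, CSV outputs with full parameter echo
cellpol batch simulated/*.tif --out results/

# inspect the shipped defaults (bandpass 0.13–0.9 μm, background 2.6 μm)
cellpol validate-config
```

Key flags: `--pixel-size`, `--band-low`, `--band-high`, `--bg-radius`,
`--min-area`, `--seed`, `--out`. Batch runs are configured via a YAML
file (`cellpol validate-config --config my.yaml`); the shipped default
is `src/cellpol/data/default_config.yaml`.

## Acceptance

The acceptance criteria are property- and synthetic-recovery-based and
implemented one test per criterion in `tests/test_acceptance.py`
(Otsu-oracle equivalence, planted-asymmetry recovery, cluster-count
recovery, Pearson/Manders closed forms, Costes threshold properties,
overlap monotonicity, pipeline determinism, bandpass linearity).

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

There are no numeric report targets (the study's printed numbers derive
from real primary-cell microscopy with no deposited raw data), so the
script writes an empty JSON object after an end-to-end smoke check.

## Conventions

- Coordinates are (x = column, y = row), origin top-left, pixel centres
  at integer positions; all physical parameters are in μm and converted
  through the image pixel size (default 0.08 μm/px in the simulator).
- Undefined metrics (e.g. half-width with no clusters) are NaN, never 0.
- Intensities stay floating point; quantisation to uint16 happens only
  at TIFF export.
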