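# cellpol default configuration (schema_version 1)
#
# Values marked [published] are the constants of the analysis this
# package reimplements; values marked [artifact] are implementation
# defaults with no claimed biological provenance.

schema_version: 1

pixel_size: null          # [artifact] μm/px; null = read from image metadata
cell_radius: null         # [artifact] μm; null = nucleus equal-area radius
                          # (the nucleus-derived radius underestimates the
                          # cell; set this when the cell radius is known)
band_low: 0.13            # [published] bandpass low scale, μm
band_high: 0.9            # [published] bandpass high scale, μm
background_radius: 2.6    # [published] local background subtraction radius, μm
otsu_bins: 256            # [artifact]
min_cluster_area: 4       # [artifact] px; suppresses single-pixel noise
connectivity: 8           # [artifact]
channel_roles:            # [artifact] map roles to channel names in inputs
  nucleus: nucleus
  compartment_a: puncta
  compartment_b: puncta_2
coloc_regression: orthogonal   # [artifact] orthogonal | ols
coloc_mask_shape: circle       # [artifact] circle | rectangle
coloc_padding: 0.0             # [artifact] μm
seed: 0                        # [artifact]
output_dir: results            # [artifact]
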