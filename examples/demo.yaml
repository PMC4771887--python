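# Quick end-to-end demo: uniform 160 mm soft-tissue cylinder on a
# downscaled detector, scatter added by the grouped-kernel model,
# corrected with 5 MLEM iterations, reconstructed with Shepp-Logan 0.6.
# Runs in a few seconds on one CPU:
#   cbctscatter run --config examples/demo.yaml --outdir out/demo

geometry:
  n_rows: 48
  n_cols: 160
  n_views: 36
  pixel_pitch_mm: 1.6

phantom:
  diameter_mm: 160.0
  voxel_size_mm: 2.5
  height_mm: 40.0

kernels:
  t_max: 200
  grid_size: 121

mlem:
  iterations: 5

recon:
  filter: shepp-logan
  cutoff: 0.6
  n_pixels: 80
  voxel_size_mm: 2.5
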