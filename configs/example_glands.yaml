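# Whole-mount gland scene: 9 glands spanning the full branch-count range.
sample_id: demo
scene:
  kind: glands
  volume_shape_voxels: [28, 768, 288]
  voxel_preset: whole_mount        # (7, 1.52, 1.52) µm; or "section"
  n_glands: 9
  branch_counts: [0, 1, 2, 3, 4, 5, 6, 7, 8]
  gland_length_range_um: [90, 160]
  tortuosity: 0.15
  lif_volume_fraction: 0.3
  seed: 42
imaging:
  psf_sigma_um: [2.0, 1.0, 1.0]
  background_level: 8.0
  poisson_gain: 1.0
  gaussian_sd: 3.0
  bit_depth: 16
  amplitude: 120.0
channels: [gland_marker, lif]
segmentation:
  sphere_diameter_um: 30.0
  threshold: otsu
  min_volume_voxels: 50
skeleton:
  min_spur_length_um: null         # null = 2x mean gland radius
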