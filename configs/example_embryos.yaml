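# Section-stack embryo scene: two blastocysts at known axis angles.
sample_id: embryos
scene:
  kind: embryos
  volume_shape_voxels: [100, 256, 128]
  voxel_preset: section            # (1.5, 1.52, 1.52) µm
  embryo_angles_deg: [24.3, 88.6]
  seed: 7
imaging: {}
channels: [nuclei]
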