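# small, fast demo run: 4 animals, coarse phantoms
seed: 0
out_dir: runs/demo
n_animals: 4
snr: 30.0
phase0_jitter: 20.0
grid_shape: [3, 3]
region_voxels:
  PHE: [0, 1]
  ATNE: [1, 0]
  CONTRA: [2, 2]
phantom_voxel_mm: 1.0
seg_tolerance: 25.0
seg_connectivity: 26
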