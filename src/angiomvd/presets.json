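{
  "version": 2,
  "comment": "Synthetic phantom presets. 'normal' emulates sparse, smooth, uniform-caliber stomach-wall vasculature with regular bifurcations; 'tumor' emulates dense, tortuous, irregular-caliber angiogenic networks crowded toward an outer shell; 'tumor_heterogeneous' replaces the surface crowding with a strong depth gradient for slice-sensitivity studies. Densities are calibrated so ground-truth centerline MVD over random 100^3-voxel VOIs falls in [2.87, 9.52]e-4 (normal) and [9.53, 20.72]e-4 (tumor).",
  "presets": {
    "normal": {
      "domain_shape": [160, 160, 160],
      "n_roots": 40,
      "branching_prob": 0.8,
      "segment_length_voxels": [18.0, 26.0],
      "radius_root_voxels": 3.0,
      "radius_decay": 0.85,
      "radius_jitter": 0.0,
      "tortuosity": 0.04,
      "gap_count": 0,
      "surface_bias": 0.0,
      "shell_thickness": 30,
      "intensity_vessel": 100.0,
      "intensity_background": 20.0,
      "noise_sd": 4.0,
      "max_generations": 1,
      "boundary_margin": 6
    },
    "tumor": {
      "domain_shape": [160, 160, 160],
      "n_roots": 168,
      "branching_prob": 1.0,
      "segment_length_voxels": [14.0, 18.0],
      "radius_root_voxels": 2.0,
      "radius_decay": 0.8,
      "radius_jitter": 0.4,
      "tortuosity": 0.25,
      "gap_count": 0,
      "surface_bias": 0.7,
      "shell_thickness": 26,
      "shell_inset": 30,
      "intensity_vessel": 100.0,
      "intensity_background": 20.0,
      "noise_sd": 4.0,
      "max_generations": 1,
      "boundary_margin": 6
    },
    "tumor_heterogeneous": {
      "domain_shape": [160, 160, 160],
      "n_roots": 120,
      "branching_prob": 1.0,
      "segment_length_voxels": [14.0, 18.0],
      "radius_root_voxels": 2.0,
      "radius_decay": 0.8,
      "radius_jitter": 0.4,
      "tortuosity": 0.25,
      "gap_count": 0,
      "surface_bias": 0.0,
      "shell_thickness": 30,
      "depth_gradient": 3.0,
      "intensity_vessel": 100.0,
      "intensity_background": 20.0,
      "noise_sd": 4.0,
      "max_generations": 1,
      "boundary_margin": 6
    }
  }
}
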