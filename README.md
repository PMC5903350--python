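# angiomvd

Quantifying tumor angiogenesis from 3D angiographic volumes with a
**3D microvessel density (MVD)** statistic based on vessel centerlines.

Classical MVD counts vessel cross-sections in a single histological slice or
microscope field, which makes the number depend on which slice was chosen,
on the magnification, and on vessel caliber. Given a volumetric image of
contrast-filled vasculature (e.g. synchrotron phase-contrast micro-CT at
~9 µm voxels), a 3D alternative is to reduce every vessel to its 1-voxel-wide
centerline and measure, for a volume of interest (VOI) *V*,

```
            Σ voxels on the vessel centerline inside V
MVD_3D  =  ─────────────────────────────────────────────
            Σ voxels in V
```

Because a centerline has unit width everywhere, this ratio measures total
vessel *length* per unit volume: it is insensitive to vessel caliber (a tube
of radius 2 and one of radius 8 contribute equally per unit length), it sees
the whole VOI rather than one slice, and it grows with genuine angiogenic
sprouting. Values are conventionally reported ×10⁻⁴ (centerline voxels per
100³-voxel VOI ≈ value × 100).

The package implements the full chain and everything needed to validate it:

| module | what it does |
| --- | --- |
| `angiomvd.volio` | TIFF-stack / NIfTI / raw volume I/O, VOI extraction, seeded random VOI sampling |
| `angiomvd.recon` | parallel-beam forward projection and filtered back projection (Ram-Lak, optional Hamming) |
| `angiomvd.vesselseg` | microvessel enhancement by grayscale morphological reconstruction (h-dome / top-hat), global Otsu segmentation |
| `angiomvd.skeleton` | 3D parallel-thinning centerlines, skeleton graphs, terminal-branch pruning |
| `angiomvd.mvd` | the centerline MVD plus the rival metrics it is compared against (2D slice counts, 3D vessel counts, voxel fractions) |
| `angiomvd.groupstats` | per-group summaries and pooled/Welch two-sample t-tests |
| `angiomvd.synthvessel` | synthetic vascular phantoms with ground-truth centerlines ("normal" and "tumor" presets, four metric-contrast model cases) |
| `angiomvd.surface` | marching-cubes surface meshes, STL/PLY export |
| `angiomvd.pipeline` | end-to-end runs from a single config with a machine-readable report |

A thin CLI (`angiomvd convert / segment / skeleton / mvd / synth / compare /
mesh / run`) wraps the library for shell use.

## Worked example

```python
from angiomvd import (make_group_phantoms, sample_vois, segment_vessels,
                      skeletonize_3d, prune_skeleton, mvd_centerline_3d,
                      ground_truth_mvd, t_test_two_sample)

values = {}
for preset in ("normal", "tumor"):
    phantom = make_group_phantoms(preset, n_samples=1, seed=1)[0]
    vois = sample_vois(phantom.volume.shape, n=10, shape=(100, 100, 100), seed=11)
    values[preset] = [ground_truth_mvd(phantom, v).value_e4 for v in vois]

res = t_test_two_sample(values["tumor"], values["normal"],
                        label_a="tumor", label_b="normal")
print(res.summary_a["mean"], res.summary_b["mean"], res.p_value)
```

prints (running `examples/04_group_comparison.py`):

```
 normal: MVD x 1e4 in [6.41, 9.17]
  tumor: MVD x 1e4 in [12.85, 19.60]
tumor mean 16.63 vs normal mean 7.78
t = 11.99, df = 18, p = 5.13e-10
```

Per-VOI centerline densities of the healthy phantom sit in the
2.87–9.52 × 10⁻⁴ band and the tumor phantom in 9.53–20.72 × 10⁻⁴; the pooled
t-test separates the groups decisively. `examples/` contains one short
script per capability (phantom generation, segmentation + skeletonization,
the three-metric contrast, group comparison, the tomographic round trip,
mesh export), each printing the numbers it computes and what they mean.

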