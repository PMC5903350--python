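# Methods

## The statistic

The package quantifies vascular density in a 3D angiographic volume as the
ratio of vessel-centerline voxels to total voxels inside an axis-aligned
cubic volume of interest (VOI, default 100³ voxels):

```
MVD_3D = (# centerline voxels in VOI) / (# voxels in VOI)
```

A centerline is one voxel wide everywhere, so the numerator is (up to
discretization) the total vessel length in voxel units: the statistic
measures length density, not volume density. That is what makes it robust
to the two failure modes of the alternatives it is compared against:

* **2D slice counts** (the histology protocol: count vessel cross-sections
  in one slice) depend on which slice is chosen whenever the network is
  depth-heterogeneous;
* **3D vessel counts** (connected components per VOI) are blind to length,
  caliber and curvature — one connected tree always scores 1;
* **voxel fractions** (vessel voxels per VOI voxel) scale with the *square*
  of vessel radius, so caliber dominates biology.

All three rivals are implemented in `angiomvd.mvd` so the contrast can be
demonstrated rather than asserted; values are exact integer ratios with a
×10⁻⁴ display convention.

### Conventions

Grids are indexed (z, y, x), 0-based, half-open; VOIs are open on their far
faces; the slice index of the 2D metric is 1-based within the VOI ("slice
number 10" = array index origin_z + 9). Voxels are isotropic (default
9 µm); anisotropic headers are rejected rather than resampled, because every
downstream quantity is a voxel count and silent resampling would change the
statistic. Foreground connectivity is 26, background 6, throughout; the 2D
slice metric uses 8-connectivity in-plane. Components touching VOI faces
are counted — the centerline numerator counts boundary voxels too, so
excluding border components would make the metrics incomparable.

## The analysis chain

1. **Reconstruction** (`recon`) — slice-by-slice parallel-beam filtered back
   projection: ramp filtering in the frequency domain, linear-interpolation
   backprojection, π/n_angles scaling (skimage's `radon`/`iradon` behind the
   module surface). A synchrotron beam is near-parallel, so no fan/cone
   geometry is modeled. Ram-Lak is the default filter with an optional
   Hamming apodization; the region of confidence is the inscribed circle
   and values outside it are zero. The forward projector exists so the
   inversion can be tested end-to-end: on a 64³ vessel phantom at 180
   angles the round-trip RMSE is ~3.8% of the dynamic range and the
   recovered MVD is within a few percent of the mask-derived value.

2. **Enhancement** (`vesselseg`) — microvessels a few voxels wide sit at
   intermediate gray levels between soft tissue and large contrast-filled
   vessels, so one global threshold loses them. Grayscale morphological
   reconstruction (iterated geodesic dilation of a marker under the image,
   26-connectivity) provides two enhancement modes:
   * `hdome` (default): `out = v + w·(v − reconstruct(v − h, v))` boosts
     every regional maximum by its prominence capped at `h`. Defaults
     h = 10% of the dynamic range, w = 1, stored in config rather than
     hard-coded. Note the cap: an isolated spike of height 100 with h = 10
     gains exactly 10 (its marker reconstructs the spike to 90), and tall
     plateaus gain h as well — h-dome boosts are *relative* prominences.
   * `tophat_by_reconstruction`: `out = v + w·(v − reconstruct(erosion_r(v), v))`
     leaves structures wider than the radius-r ball untouched and adds the
     full height of thinner ones. This is the mode that makes a dim
     radius-1 microvessel and a bright radius-6 vessel separable by a
     single threshold (demonstrated in the test suite); the additive h-dome
     cannot, because it can only add a structure's prominence over the
     local tissue envelope, which is bounded by the tissue variation.

3. **Segmentation** (`vesselseg.otsu_threshold`) — global Otsu on the whole
   (enhanced) volume: 256 uniform histogram bins spanning [min, max],
   threshold at the bin center maximizing between-class variance, ties
   toward the lower bin, mask = `volume > threshold`. Binning over the data
   range makes the threshold shift-equivariant and the mask shift-invariant.
   The pipeline thresholds the enhanced volume and records that choice in
   the run report. The implementation is a 20-line vectorized routine so the
   binning convention is exactly as documented; tests check it against both
   an exhaustive brute-force search and skimage's implementation.

4. **Centerline** (`skeleton`) — 3D parallel thinning (Lee–Kashyap–Chu
   medial-axis thinning, 6 directional subiterations with simple-point
   preservation, via skimage) produces a 1-voxel-wide curve skeleton that
   preserves topology. One repair is applied on top: the stock algorithm
   annihilates certain degenerate blobs outright (a 2×2×2 cube thins to
   nothing), so one representative voxel is restored per lost 26-component —
   no object may vanish. Thinning reacts to every surface bump, so
   **pruning** removes terminal branches shorter than `min_branch_len`
   voxels (default 5; no published value exists for this threshold, so it is
   exposed in config and recorded in every report). Pruning is a single
   simultaneous pass: length-based removal of endpoint-to-junction paths,
   whole-component removal only for isolated paths shorter than the
   threshold (a lone vessel is never eroded from its free ends), junctions
   that drop to degree 2 merge into through-branches on the next graph
   build. Iterated pruning is deliberately not the default — repeated
   passes would eat genuine short side-branches.

   The skeleton graph convention: nodes are voxels with 26-neighbor degree
   ≠ 2 (endpoints ≤ 1, junctions ≥ 3), branches are maximal degree-2 paths,
   branch length = interior voxel count, so branch lengths + node count
   always equals the voxel count. A straight line of N voxels is 2
   endpoints plus one branch of length N − 2.

5. **Statistics** (`groupstats`) — per-group mean/min/max/sd (n−1), and a
   two-sided two-sample t-test: pooled variance by default (df = nₐ+n_b−2),
   Welch with Satterthwaite df available and preferable under variance
   heterogeneity. The pooled variant refuses zero pooled variance instead
   of returning t = ±∞. Reports carry an explicit unit-of-analysis label
   (VOI by default) because pooling VOIs across animals versus per-animal
   averaging changes the meaning of n. 2000-replicate null simulations put
   the empirical type-I error at α = 0.05 near 0.05 (within [0.03, 0.07]).

## The phantom generator

`synthvessel` grows branching centerline trees: unit-length steps whose
direction receives Gaussian perpendicular jitter scaled by `tortuosity`;
per-segment branching with probability `branching_prob` into two children
rotated ±~35° and scaled by `radius_decay`; reflection at a boundary
margin. Polylines are rasterized by dense sampling followed by greedy
simplification to a *minimal 26-connected path* — this matters, because a
naive rasterization yields a 6-connected staircase with up to 3× more
voxels, which would bias every comparison between ground truth and a
thinned (26-connected) skeleton. Tubes are the union of radius-r balls
around each radius class, computed with exact Euclidean distance
transforms. Intensities are vessel = 100, soft-tissue background = 20,
additive Gaussian noise (default sd 4, i.e. 5% of the contrast); all
randomness flows from a single seeded generator, so phantoms are
bit-reproducible.

Optional **gaps** model detection misses: breaks carved out of the tube
with a ball of radius r+1.5 along a run of centerline voxels. Carving
verifies that each break really severs the vessel (a cut too close to a
junction can be bridged by a neighboring tube) and prefers cuts whose two
sides both remain substantial (≥ 200 voxels), retrying candidate positions
ordered by clearance from other branches.

**Presets** (versioned in `presets.json`, not code):

* `normal` — 40 sparse, low-tortuosity, uniform-caliber trees in a 160³
  domain, stratified seeding; calibrated so per-VOI ground-truth MVD of
  random 100³ VOIs falls in 2.87–9.52 × 10⁻⁴.
* `tumor` — 168 short, tortuous, caliber-jittered trees, 70% seeded in a
  26-voxel outer shell (inset from face edges so the crowding is even);
  calibrated to 9.53–20.72 × 10⁻⁴ with shell-adjacent VOIs measurably
  denser than core VOIs, mirroring the surface concentration of tumor
  angiogenesis.
* `tumor_heterogeneous` — surface bias replaced by a linear density
  gradient along z (density ∝ 1 + 3z/nz), used to demonstrate the
  slice-sensitivity of 2D counting.

Four **model cases** isolate what each metric responds to, everything else
held fixed: I bends the reference tree's branches with an endpoint-pinned
sinusoid (curvature adds arc length, connectivity preserved); II is the
reference tree at tube radius 2; III is the *identical centerline* at
radius 4; IV is case II with three verified discontinuities. The case tree
is regrown (deterministically, from the seed) until it is self-clear — no
two branches within 7 voxels away from their shared junction and no branch
folded back by a wall reflection — so that the tube set is a genuine tree
and each carved gap changes the component count by exactly one.

### What the phantoms do and do not emulate

They reproduce the features the analysis chain is sensitive to: bright
tubular trees over darker tissue, few-voxel microvessel calibers, noise,
surface crowding, discontinuities. They do not model phase-contrast
physics (Fresnel fringes, phase retrieval), ring or motion artifacts,
contrast-agent sedimentation, or anatomically realistic (e.g. flow-
optimized) branching. Passing tests therefore demonstrate correctness of
the measurement chain on ideal-but-noisy tubular geometry, not robustness
to every artifact of real beamline data.

## Numerical and design choices

* Problem sizes were chosen to keep the full validation suite at a few
  minutes on one CPU: 120–160³ phantom domains, 64³ tomography phantoms,
  20-tree accuracy sweeps, 2000-replicate null simulations. Accuracy
  conclusions were unchanged in spot checks at larger sizes.
* End-to-end accuracy: across 20 random low-noise trees, pipeline MVD per
  100³ VOI tracks ground truth with ~2–3% mean and < 10% maximum absolute
  error; the residual bias is thinning's retraction of tube ends by about
  one radius and pruning of sub-threshold spurs.
* VOI sampling is uniform without replacement over center voxels; VOIs may
  overlap (only centers are distinct). Validity under a region mask is
  membership of the *center* voxel — the simplest testable reading of
  "a VOI in the outer layer".
* Degenerate inputs fail loudly and specifically: constant volumes for
  Otsu, marker > mask for reconstruction, out-of-bounds VOIs (no silent
  clipping), anisotropic headers, infeasible VOI sampling, zero pooled
  variance.
* The empty mask is not an error for skeletonization (an empty skeleton
  with a flag), because empty segmentations are a legitimate pipeline
  outcome the report should surface, not crash on.

## Known limitations

* Thinning shortens tubes by roughly one radius at each open end, so the
  centerline MVD carries a small caliber-dependent negative bias (a few
  percent for radius ≤ 4 vessels of realistic length; the diameter-
  invariance test bounds it at < 10% across radii 2–8).
* The 2D slice-count metric counts 8-connected components with no minimum
  size, magnification model, or border exclusion; it emulates the
  automatable core of the histology protocol, not a pathologist's judgment.
* Pruning is length-based only; it cannot distinguish a genuine short
  side-branch from a surface artifact of the same length.
* FBP assumes parallel-beam geometry and ignores phase effects; sinograms
  from real beamlines need phase retrieval and ring correction upstream of
  this package.
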