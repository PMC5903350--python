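"""Synthetic vascular phantoms with ground-truth centerlines.

The generator emulates what a reconstructed propagation-based phase-contrast
CT volume of contrast-filled vasculature looks like to the analysis chain:
bright tubular trees (large vessels plus few-voxel-wide microvessels) on a
darker soft-tissue background with additive Gaussian noise, at ~9 µm
isotropic voxels. Two families of presets mirror the biology:

* ``normal`` — sparse, smooth trees of uniform caliber with regular
  bifurcations, seeded uniformly through the wall;
* ``tumor`` — denser, tortuous trees of irregular caliber, crowded toward an
  outer shell (angiogenic activity concentrates at the tumor surface).

Trees are grown as branching centerline polylines (unit steps with a random
perpendicular direction jitter controlled by ``tortuosity``), rasterized to
a 26-connected voxel path, and dilated to tubes of per-branch radius via
exact Euclidean distance transforms. Optional gaps carve zero-intensity
breaks that model detection misses. Every phantom carries its ground truth
(centerline voxels, tube mask, branch polylines), so each analysis stage can
be scored against what the generator actually drew.

All randomness flows from ``spec.seed`` through a single
``numpy.random.Generator``; identical specs produce bit-identical phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage

from .errors import SpecError
from .mvd import MVDResult
from .types import VOI, BinaryVolume, VolumeImage

__all__ = [
    "VesselTreeSpec",
    "PhantomOutput",
    "generate_tree",
    "make_model_cases",
    "make_case",
    "make_group_phantoms",
    "load_presets",
    "ground_truth_mvd",
]

_STEP = 0.9  # polyline step length, voxels
_RASTER_DS = 0.45  # dense sampling interval for rasterization


@dataclass
class VesselTreeSpec:
    """Parametric description of a synthetic vascular tree population.

    Units are voxels unless noted. ``tortuosity`` is the standard deviation
    of the random perpendicular direction jitter per unit step (0 = straight
    segments); ``surface_bias`` is the fraction of roots seeded within
    ``shell_thickness`` of the domain boundary; ``depth_gradient`` g biases
    root density linearly along z (density ∝ 1 + g·z/nz), for building
    depth-heterogeneous phantoms. Radii decay by ``radius_decay`` per
    branching generation but never below 1 voxel.
    """

    domain_shape: tuple[int, int, int] = (128, 128, 128)
    n_roots: int = 6
    branching_prob: float = 0.7
    segment_length_voxels: tuple[float, float] = (18.0, 28.0)
    radius_root_voxels: float = 3.0
    radius_decay: float = 0.8
    radius_jitter: float = 0.0
    tortuosity: float = 0.08
    gap_count: int = 0
    gap_length_voxels: tuple[float, float] = (5.0, 9.0)
    surface_bias: float = 0.0
    shell_thickness: int = 30
    shell_inset: int = 0
    depth_gradient: float = 0.0
    intensity_vessel: float = 100.0
    intensity_background: float = 20.0
    noise_sd: float = 4.0
    seed: int = 0
    max_generations: int = 3
    boundary_margin: int = 6
    branch_angle_deg: float = 35.0
    root_length_scale: float = 1.0

    def __post_init__(self) -> None:
        self.domain_shape = tuple(int(v) for v in self.domain_shape)
        if self.radius_root_voxels < 1:
            raise SpecError("radii must be >= 1 voxel")
        if any(d <= 2 * self.boundary_margin for d in self.domain_shape):
            raise SpecError(
                f"domain {self.domain_shape} too small for boundary margin "
                f"{self.boundary_margin}"
            )
        if self.radius_root_voxels * 2 + 2 >= min(self.domain_shape):
            raise SpecError("root radius too large for the domain")
        if not 0 <= self.surface_bias <= 1:
            raise SpecError("surface_bias must lie in [0, 1]")
        if self.gap_count > 0 and self.gap_length_voxels[1] >= self.segment_length_voxels[0]:
            raise SpecError("gaps must not exceed segment lengths")


@dataclass
class Polyline:
    """One vessel branch: float centerline points and a tube radius."""

    points: np.ndarray  # (n, 3) float (z, y, x)
    radius: float
    tree_id: int
    generation: int

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class PhantomOutput:
    """A generated phantom plus its ground truth."""

    volume: VolumeImage
    mask_truth: BinaryVolume
    centerline_mask: np.ndarray  # bool, 1-voxel-wide truth centerline
    polylines: list[Polyline]
    spec: VesselTreeSpec
    branch_count_truth: int = 0
    component_count_truth: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def centerline_truth(self) -> np.ndarray:
        """(N, 3) integer (z, y, x) coordinates of the true centerline."""
        return np.argwhere(self.centerline_mask)


# ---------------------------------------------------------------- growth ---


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    while np.linalg.norm(v) < 1e-9:
        v = rng.normal(size=3)
    return _unit(v)


def _perpendicular(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v = v - np.dot(v, d) * d
    n = np.linalg.norm(v)
    if n < 1e-9:
        v = np.array([d[1], -d[0], 0.0])
        n = np.linalg.norm(v)
        if n < 1e-9:
            v, n = np.array([0.0, d[2], -d[1]]), np.linalg.norm(
                np.array([0.0, d[2], -d[1]])
            )
    return v / n


def _rotate(d: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    # Rodrigues rotation of unit vector d about unit axis
    return _unit(
        d * np.cos(angle)
        + np.cross(axis, d) * np.sin(angle)
        + axis * np.dot(axis, d) * (1 - np.cos(angle))
    )


def _sample_root_positions(spec: VesselTreeSpec, rng: np.random.Generator) -> np.ndarray:
    """Root seed points; stratified so trees spread evenly through the domain."""
    shape = np.array(spec.domain_shape, dtype=float)
    m = spec.boundary_margin
    n = spec.n_roots
    in_shell = rng.random(n) < spec.surface_bias
    pts = np.empty((n, 3))
    # stratify the interior points over a coarse grid to avoid clumping
    interior_idx = np.flatnonzero(~in_shell)
    if interior_idx.size:
        k = int(np.ceil(interior_idx.size ** (1 / 3)))
        cells = [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]
        order = rng.permutation(len(cells))[: interior_idx.size]
        for j, ci in zip(interior_idx, order):
            cell = np.array(cells[ci], dtype=float)
            frac = (cell + rng.random(3)) / k
            pts[j] = m + frac * (shape - 2 * m)
    shell_idx = np.flatnonzero(in_shell)
    if shell_idx.size:
        # stratify shell roots over the 6 faces and a coarse 2D grid per face
        # so surface crowding is even rather than clumped
        faces = rng.permutation(np.arange(shell_idx.size) % 6)
        k2 = int(np.ceil(np.sqrt(max(shell_idx.size / 6, 1))))
        cells2 = [(a, b) for a in range(k2) for b in range(k2)]
        per_face_order = {f: rng.permutation(len(cells2)) for f in range(6)}
        per_face_count = {f: 0 for f in range(6)}
        t = spec.shell_thickness
        for j, f in zip(shell_idx, faces):
            axis, side = f % 3, f // 3
            ci = per_face_order[f][per_face_count[f] % len(cells2)]
            per_face_count[f] += 1
            cell = np.array(cells2[ci], dtype=float)
            frac2 = (cell + rng.random(2)) / k2
            p = np.empty(3)
            other = [a for a in range(3) if a != axis]
            inset = max(m, spec.shell_inset)
            for o, fr in zip(other, frac2):
                p[o] = inset + fr * (shape[o] - 2 * inset)
            depth = m + rng.random() * max(t - m, 1)
            p[axis] = depth if side == 0 else shape[axis] - 1 - depth
            pts[j] = p
    if spec.depth_gradient:
        g = spec.depth_gradient
        nz = shape[0]
        # resample z with linear density 1 + g * z / nz via inverse CDF
        u = rng.random(n)
        if abs(g) > 1e-12:
            a = g / (2 * nz)
            z = (-1 + np.sqrt(1 + 4 * a * u * (nz + g * nz / 2))) / (2 * a)
        else:
            z = u * nz
        pts[:, 0] = np.clip(z, m, nz - 1 - m)
    return pts


def _grow_tree(
    spec: VesselTreeSpec,
    rng: np.random.Generator,
    start: np.ndarray,
    tree_id: int,
) -> list[Polyline]:
    lo = np.full(3, float(spec.boundary_margin))
    hi = np.array(spec.domain_shape, dtype=float) - 1 - spec.boundary_margin
    polylines: list[Polyline] = []
    stack = [(start.copy(), _random_direction(rng), float(spec.radius_root_voxels), 0)]
    while stack:
        pos, d, radius, gen = stack.pop()
        seg_len = rng.uniform(*spec.segment_length_voxels)
        if gen == 0:
            seg_len *= spec.root_length_scale
        n_steps = max(2, int(round(seg_len / _STEP)))
        pts = [pos.copy()]
        for _ in range(n_steps):
            if spec.tortuosity > 0:
                d = _unit(d + spec.tortuosity * rng.normal(size=3))
            nxt = pos + _STEP * d
            for ax in range(3):  # reflect at the domain margin
                if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                    d[ax] = -d[ax]
                    nxt[ax] = np.clip(pos[ax] + _STEP * d[ax], lo[ax], hi[ax])
            pos = nxt
            pts.append(pos.copy())
        polylines.append(
            Polyline(points=np.array(pts), radius=radius, tree_id=tree_id, generation=gen)
        )
        if gen + 1 > spec.max_generations:
            continue
        if rng.random() < spec.branching_prob:
            axis = _perpendicular(d, rng)
            angle = np.deg2rad(spec.branch_angle_deg) * (0.8 + 0.4 * rng.random())
            child_r = max(1.0, radius * spec.radius_decay)
            if spec.radius_jitter > 0:
                jit = 1.0 + spec.radius_jitter * (2 * rng.random(2) - 1)
            else:
                jit = np.ones(2)
            stack.append((pos.copy(), _rotate(d, axis, angle), max(1.0, child_r * jit[0]), gen + 1))
            stack.append((pos.copy(), _rotate(d, axis, -angle), max(1.0, child_r * jit[1]), gen + 1))
        else:
            stack.append((pos.copy(), d.copy(), radius, gen + 1))
    return polylines


# ----------------------------------------------------------- rasterization ---


def _rasterize_polyline(points: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Dense-sample a polyline and floor to voxels; consecutive voxels are
    26-adjacent. Returns (n, 3) int coordinates (consecutive duplicates removed)."""
    segs = np.diff(points, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    out = [points[0]]
    for p0, s, ln in zip(points[:-1], segs, lens):
        n = max(1, int(np.ceil(ln / _RASTER_DS)))
        t = (np.arange(1, n + 1) / n)[:, None]
        out.append(p0 + t * s)
    dense = np.vstack(out)
    vox = np.floor(dense + 0.5).astype(int)
    vox = np.clip(vox, 0, np.array(shape) - 1)
    keep = np.ones(len(vox), dtype=bool)
    keep[1:] = np.any(np.diff(vox, axis=0) != 0, axis=1)
    chain = vox[keep]
    if len(chain) < 3:
        return chain
    # greedy simplification to a minimal 26-connected path: drop staircase
    # voxels whose successor is still 26-adjacent to the last kept voxel,
    # so voxel counts match the convention of a thinned centerline
    kept = [chain[0]]
    i = 1
    n = len(chain)
    while i < n:
        j = i
        while j + 1 < n and np.abs(chain[j + 1] - kept[-1]).max() <= 1:
            j += 1
        kept.append(chain[j])
        i = j + 1
    return np.array(kept)


def _break_solid_blocks(cl: np.ndarray) -> None:
    """Remove voxels until no 2x2x2 solid block of centerline voxels remains.

    Prefers voxels whose removal keeps the local 26-neighborhood connected.
    Operates in place; needed only where two branches run flush against each
    other, which is rare."""
    for _ in range(64):
        solid = (
            cl[:-1, :-1, :-1]
            & cl[1:, :-1, :-1]
            & cl[:-1, 1:, :-1]
            & cl[:-1, :-1, 1:]
            & cl[1:, 1:, :-1]
            & cl[1:, :-1, 1:]
            & cl[:-1, 1:, 1:]
            & cl[1:, 1:, 1:]
        )
        corners = np.argwhere(solid)
        if corners.size == 0:
            return
        for cz, cy, cx in corners:
            block = [
                (cz + a, cy + b, cx + c) for a in (0, 1) for b in (0, 1) for c in (0, 1)
            ]
            removed = False
            for v in block:
                if not cl[v]:
                    removed = True
                    break
                if _is_locally_simple(cl, v):
                    cl[v] = False
                    removed = True
                    break
            if not removed:
                cl[block[0]] = False


def _is_locally_simple(cl: np.ndarray, v: tuple[int, int, int]) -> bool:
    """True if removing ``v`` keeps its 26-neighborhood foreground connected."""
    z, y, x = v
    zs = slice(max(z - 1, 0), z + 2)
    ys = slice(max(y - 1, 0), y + 2)
    xs = slice(max(x - 1, 0), x + 2)
    nb = cl[zs, ys, xs].copy()
    nb[min(z, 1), min(y, 1), min(x, 1)] = False
    if not nb.any():
        return False
    _, n = ndimage.label(nb, structure=np.ones((3, 3, 3), dtype=bool))
    return n == 1


def _tubes_from_centerline(
    shape: tuple[int, int, int],
    voxels_by_radius: dict[int, list[tuple[int, int, int]]],
) -> np.ndarray:
    """Union of radius-r balls around the centerline voxels of each radius class
    (exact Euclidean distance transform per radius class)."""
    mask = np.zeros(shape, dtype=bool)
    for r, voxels in voxels_by_radius.items():
        seeds = np.zeros(shape, dtype=bool)
        idx = np.asarray(voxels)
        seeds[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        if r <= 0:
            mask |= seeds
            continue
        dist = ndimage.distance_transform_edt(~seeds)
        mask |= dist <= r + 1e-9
    return mask


# ------------------------------------------------------------------- gaps ---


def _carve_gaps(
    spec: VesselTreeSpec,
    rng: np.random.Generator,
    polylines: list[Polyline],
    centerline: np.ndarray,
    mask: np.ndarray,
) -> None:
    """Carve ``spec.gap_count`` zero-intensity breaks (detection misses)."""
    if spec.gap_count == 0:
        return
    # prefer internal branches: severing one detaches a whole subtree, so
    # both sides of the break remain substantial vessels (a cut near a leaf
    # tip would leave only a tiny stub)
    starts = [pl.points[0] for pl in polylines]

    def _is_internal(pl: Polyline) -> bool:
        return any(
            np.linalg.norm(pl.points[-1] - s) < 1e-6 for s in starts
        )

    eligible = sorted(
        (pl for pl in polylines if pl.arc_length > 3 * spec.gap_length_voxels[1]),
        key=lambda pl: (not _is_internal(pl), pl.generation == 0, -pl.arc_length),
    )
    if not eligible:
        raise SpecError("no branch long enough to host the requested gaps")
    per_pl: dict[int, int] = {}
    targets = []
    for g in range(spec.gap_count):
        pl = eligible[g % len(eligible)]
        per_pl[id(pl)] = per_pl.get(id(pl), 0) + 1
        targets.append(pl)
    from scipy.spatial import cKDTree

    structure = ndimage.generate_binary_structure(3, 3)

    def _carve_at(target_mask: np.ndarray, gap_vox: np.ndarray, r_carve: float) -> None:
        # carve a tube-severing ball set inside a padded local box
        pad = int(np.ceil(r_carve)) + 1
        lo_c = np.maximum(gap_vox.min(axis=0) - pad, 0)
        hi_c = np.minimum(gap_vox.max(axis=0) + pad + 1, spec.domain_shape)
        box = tuple(slice(a, b) for a, b in zip(lo_c, hi_c))
        local = np.zeros(tuple(hi_c - lo_c), dtype=bool)
        rel = gap_vox - lo_c
        local[rel[:, 0], rel[:, 1], rel[:, 2]] = True
        dist = ndimage.distance_transform_edt(~local)
        target_mask[box] &= dist > r_carve

    counts = {k: 0 for k in per_pl}
    n_before = ndimage.label(mask, structure=structure)[1]
    for pl in targets:
        counts[id(pl)] += 1
        k, total = counts[id(pl)], per_pl[id(pl)]
        vox = _rasterize_polyline(pl.points, spec.domain_shape)
        gap_len = int(round(rng.uniform(*spec.gap_length_voxels)))
        # candidate positions inside this gap's section of the branch,
        # preferred where the other branches are farthest away so the break
        # is not bridged by a neighboring vessel
        lo = int(len(vox) * (k - 0.4) / (total + 1))
        hi = int(len(vox) * (k + 0.4) / (total + 1))
        lo = max(lo, gap_len + 3)
        hi = min(hi, len(vox) - gap_len - 3)
        if hi <= lo:
            lo, hi = max(1, len(vox) // 2), max(2, len(vox) // 2 + 1)
        others = [
            _rasterize_polyline(q.points, spec.domain_shape)
            for q in polylines
            if q is not pl
        ]
        if others:
            tree = cKDTree(np.vstack(others))
            clearance, _ = tree.query(vox[lo:hi], k=1)
            order = lo + np.argsort(-clearance)
        else:
            order = np.array([(lo + hi) // 2])
        # carve at the best candidate that really severs the vessel
        # (a cut too close to a junction can merge with a neighboring tube
        # and fail to disconnect anything)
        accepted = False
        for require_bulk in (True, False):
            for center in order[:10]:
                a = max(0, int(center) - gap_len // 2)
                b = min(len(vox), a + gap_len)
                trial = mask.copy()
                _carve_at(trial, vox[a:b], pl.radius + 1.5)
                lab, n_after = ndimage.label(trial, structure=structure)
                if n_after <= n_before:
                    continue
                if require_bulk:
                    # both sides of the break must stay substantial vessels,
                    # not stubs that vanish under skeleton pruning
                    sizes = np.bincount(lab.ravel())[1:]
                    if sizes.min() < 200:
                        continue
                mask[:] = trial
                n_before = n_after
                accepted = True
                break
            if accepted:
                break
        if not accepted:  # fall back to the max-clearance cut even if it merges
            a = max(0, int(order[0]) - gap_len // 2)
            b = min(len(vox), a + gap_len)
            _carve_at(mask, vox[a:b], pl.radius + 1.5)
            n_before = ndimage.label(mask, structure=structure)[1]
    centerline &= mask


# ------------------------------------------------------------ entry points ---


def generate_tree(spec: VesselTreeSpec) -> PhantomOutput:
    """Generate one phantom: grow trees, rasterize, add noise, keep the truth."""
    rng = np.random.default_rng(spec.seed)
    roots = _sample_root_positions(spec, rng)
    polylines: list[Polyline] = []
    for tree_id in range(spec.n_roots):
        polylines.extend(_grow_tree(spec, rng, roots[tree_id], tree_id))
    return _finalize(spec, rng, polylines)


def _finalize(
    spec: VesselTreeSpec, rng: np.random.Generator, polylines: list[Polyline]
) -> PhantomOutput:
    shape = spec.domain_shape
    centerline = np.zeros(shape, dtype=bool)
    by_radius: dict[int, list] = {}
    for pl in polylines:
        vox = _rasterize_polyline(pl.points, shape)
        centerline[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        r = int(round(pl.radius))
        by_radius.setdefault(r, []).extend(map(tuple, vox))
    _break_solid_blocks(centerline)
    mask = _tubes_from_centerline(shape, by_radius)
    mask |= centerline  # the centerline itself is always vessel
    _carve_gaps(spec, rng, polylines, centerline, mask)
    noise = rng.normal(0.0, spec.noise_sd, size=shape) if spec.noise_sd > 0 else 0.0
    data = np.where(mask, spec.intensity_vessel, spec.intensity_background) + noise
    volume = VolumeImage(data=data, intensity_units="synthetic phase-contrast CT")
    _, n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 3))
    return PhantomOutput(
        volume=volume,
        mask_truth=BinaryVolume(mask=mask, voxel_size_um=volume.voxel_size_um),
        centerline_mask=centerline,
        polylines=polylines,
        spec=spec,
        branch_count_truth=len(polylines),
        component_count_truth=int(n_comp),
        meta={"seed": spec.seed},
    )


# --------------------------------------------------------- model test cases ---


def _case_base_spec(domain: tuple[int, int, int], seed: int) -> VesselTreeSpec:
    return VesselTreeSpec(
        domain_shape=domain,
        n_roots=1,
        branching_prob=1.0,
        segment_length_voxels=(26.0, 34.0),
        radius_root_voxels=2.0,
        radius_decay=1.0,
        tortuosity=0.0,
        noise_sd=0.0,
        intensity_background=0.0,
        seed=seed,
        max_generations=2,
        boundary_margin=10,
        root_length_scale=1.8,
    )


def _add_curvature(polylines: list[Polyline], amplitude: float, seed: int) -> list[Polyline]:
    """Bend each branch with a smooth perpendicular sinusoid that vanishes at
    both ends, so junction points (and therefore connectivity) are preserved
    while arc length strictly grows."""
    rng = np.random.default_rng(seed + 104729)
    bent = []
    for pl in polylines:
        pts = pl.points.copy()
        chord = pts[-1] - pts[0]
        n = np.linalg.norm(chord)
        if n < 1e-9 or len(pts) < 3:
            bent.append(Polyline(pts, pl.radius, pl.tree_id, pl.generation))
            continue
        d = chord / n
        u = _perpendicular(d, rng)
        t = np.linspace(0.0, 1.0, len(pts))
        offset = amplitude * np.sin(2 * np.pi * t)[:, None] * u[None, :]
        bent.append(Polyline(pts + offset, pl.radius, pl.tree_id, pl.generation))
    return bent


def _tree_is_self_clear(
    polylines: list[Polyline], shape: tuple[int, int, int], min_dist: float = 7.0
) -> bool:
    """True if no two branches come closer than ``min_dist`` (centerline to
    centerline) away from their shared junctions — i.e. the rasterized tubes
    form a genuine tree with no incidental cycles."""
    from scipy.spatial import cKDTree

    # a branch folded back by a wall reflection can tuck its far end into
    # its own junction zone; require branches to stay reasonably straight
    for pl in polylines:
        if np.linalg.norm(pl.points[-1] - pl.points[0]) < 0.7 * pl.arc_length:
            return False
    vox = [_rasterize_polyline(pl.points, shape).astype(float) for pl in polylines]
    ends = [(pl.points[0], pl.points[-1]) for pl in polylines]
    for i in range(len(polylines)):
        tree = cKDTree(vox[i])
        for j in range(i + 1, len(polylines)):
            d, idx = tree.query(vox[j], k=1)
            close = d < min_dist
            if not close.any():
                continue
            # allow proximity near a shared junction point only
            shared = [
                p
                for p in ends[i]
                for q in ends[j]
                if np.linalg.norm(p - q) < 1e-6
            ]
            if not shared:
                return False
            jpt = shared[0]
            for vj in vox[j][close]:
                if np.linalg.norm(vj - jpt) > 1.5 * min_dist:
                    return False
    return True


def make_case(case: str, domain: tuple[int, int, int] = (100, 100, 100), seed: int = 0) -> PhantomOutput:
    """Build one of the four vessel model cases used to contrast the metrics.

    * ``I``   — the base tree bent to high curvature (same endpoints);
    * ``II``  — the base tree, tube radius 2;
    * ``III`` — the identical centerline, tube radius 4 (caliber doubled);
    * ``IV``  — case II's geometry with three carved discontinuities.
    """
    case = case.upper()
    if case not in ("I", "II", "III", "IV"):
        raise ValueError(f"unknown case {case!r}; expected I, II, III or IV")
    spec = _case_base_spec(domain, seed)
    rng = np.random.default_rng(spec.seed)
    # regrow until the tree is free of incidental branch crossings (wall
    # reflections can fold a tree onto itself); deterministic given the seed
    for _ in range(100):
        roots = _sample_root_positions(spec, rng)
        polylines = _grow_tree(spec, rng, roots[0], 0)
        if _tree_is_self_clear(polylines, spec.domain_shape):
            break
    else:
        raise SpecError("could not grow a self-clear model-case tree")
    if case == "I":
        polylines = _add_curvature(polylines, amplitude=6.0, seed=seed)
    if case == "III":
        polylines = [Polyline(pl.points, pl.radius * 2, pl.tree_id, pl.generation) for pl in polylines]
        spec.radius_root_voxels = spec.radius_root_voxels * 2
    if case == "IV":
        spec.gap_count = 3
        spec.gap_length_voxels = (7.0, 7.0)
    return _finalize(spec, rng, polylines)


def make_model_cases(domain: tuple[int, int, int] = (100, 100, 100), seed: int = 0) -> dict[str, PhantomOutput]:
    """All four model cases, keyed 'I'..'IV'."""
    return {c: make_case(c, domain=domain, seed=seed) for c in ("I", "II", "III", "IV")}


# ----------------------------------------------------------------- presets ---


def load_presets() -> dict:
    """The versioned preset parameter file shipped with the package."""
    with resources.files("angiomvd").joinpath("presets.json").open() as fh:
        return json.load(fh)


def spec_from_preset(preset: str, seed: int = 0, **overrides) -> VesselTreeSpec:
    presets = load_presets()
    if preset not in presets["presets"]:
        raise KeyError(f"unknown preset {preset!r}; have {sorted(presets['presets'])}")
    params = dict(presets["presets"][preset])
    params.update(overrides)
    for key in ("domain_shape", "segment_length_voxels", "gap_length_voxels"):
        if key in params:
            params[key] = tuple(params[key])
    return VesselTreeSpec(seed=seed, **params)


def make_group_phantoms(group: str, n_samples: int, seed: int = 0, **overrides) -> list[PhantomOutput]:
    """Generate ``n_samples`` phantoms from the named preset.

    Sample ``i`` uses seed ``seed + i`` so samples are independent but the
    whole list is reproducible from one seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return [
        generate_tree(spec_from_preset(group, seed=seed + i, **overrides))
        for i in range(n_samples)
    ]


def ground_truth_mvd(phantom: PhantomOutput, voi: VOI) -> MVDResult:
    """Centerline MVD of the generator's own centerline inside a VOI."""
    voi.check_within(phantom.centerline_mask.shape)
    numerator = int(phantom.centerline_mask[voi.slices()].sum())
    return MVDResult(
        method="centerline_3d",
        numerator=numerator,
        denominator=voi.n_voxels,
        voi=voi,
        params={"source": "ground_truth"},
    )
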