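"""Microvessel density metrics.

The primary statistic is the 3D centerline MVD: the number of vessel
centerline voxels inside a volume of interest divided by the VOI's total
voxel count,

    MVD = (# voxels on the vessel centerline in the VOI) / (# voxels in the VOI).

Because a centerline has unit width everywhere, this ratio measures the
total vessel *length* per unit volume and is insensitive to vessel caliber.
Three rival metrics are provided for comparison:

* ``slice_count_2d`` — the classical histology-style count: number of vessel
  cross-sections (8-connected components) in one z-slice of the VOI, per
  slice pixel; depends strongly on which slice is chosen.
* ``vessel_count_3d`` — number of 26-connected vessel components in the VOI,
  per VOI voxel; blind to shape, length and caliber (one connected tree
  always counts 1).
* ``voxel_fraction_3d`` — vessel voxels per VOI voxel; scales with the
  square of vessel radius, so caliber dominates it.

Values are exact ratios; ``value_e4`` reports the conventional ×10⁻⁴
display scale (centerline voxels per 100³-voxel VOI ≈ value_e4 × 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import BoundsError, FrameError
from .types import VOI, BinaryVolume, Skeleton

__all__ = [
    "MVDResult",
    "mvd_centerline_3d",
    "mvd_slice_count_2d",
    "mvd_vessel_count_3d",
    "mvd_voxel_fraction_3d",
]


@dataclass
class MVDResult:
    method: str
    numerator: int
    denominator: int
    voi: VOI
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def value_e4(self) -> float:
        """Value on the conventional ×10⁻⁴ display scale."""
        return self.value * 1e4

    def as_row(self) -> dict:
        return {
            "voi_origin": self.voi.origin,
            "voi_shape": self.voi.shape,
            "method": self.method,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "value": self.value,
            "value_e4": self.value_e4,
            **{f"param_{k}": v for k, v in self.params.items()},
        }


def _check_frame(shape: tuple[int, int, int], voi: VOI) -> None:
    try:
        voi.check_within(shape)
    except BoundsError as exc:
        raise FrameError(
            f"VOI {voi.origin}+{voi.shape} does not fit the source grid {shape}"
        ) from exc


def mvd_centerline_3d(skeleton: Skeleton, voi: VOI) -> MVDResult:
    """The 3D centerline MVD: skeleton voxels in the VOI per VOI voxel."""
    _check_frame(skeleton.source_shape, voi)
    numerator = int(skeleton.mask[voi.slices()].sum())
    return MVDResult(
        method="centerline_3d", numerator=numerator, denominator=voi.n_voxels, voi=voi
    )


def mvd_slice_count_2d(mask: BinaryVolume, voi: VOI, slice_index: int) -> MVDResult:
    """Histology-style 2D MVD on one z-slice of the VOI.

    ``slice_index`` is 1-based within the VOI ("slice number 10" is the 10th
    slice, array index ``voi.origin[0] + 9``). The numerator is the number
    of 8-connected foreground components in that slice; the denominator is
    the in-plane pixel count. Components touching the VOI faces count.
    """
    _check_frame(mask.shape, voi)
    nz = voi.shape[0]
    if not 1 <= slice_index <= nz:
        raise BoundsError(
            f"slice_index {slice_index} outside VOI z-extent 1..{nz} (1-based)"
        )
    z = voi.origin[0] + slice_index - 1
    sl = mask.mask[z, voi.slices()[1], voi.slices()[2]]
    _, n = ndimage.label(sl, structure=np.ones((3, 3), dtype=bool))
    denominator = voi.shape[1] * voi.shape[2]
    return MVDResult(
        method="slice_count_2d",
        numerator=int(n),
        denominator=denominator,
        voi=voi,
        params={"slice_index": slice_index, "connectivity": 8},
    )


def mvd_vessel_count_3d(source: Skeleton | BinaryVolume, voi: VOI) -> MVDResult:
    """Vessel-count metric: 26-connected components in the VOI per VOI voxel."""
    grid = source.mask
    _check_frame(tuple(grid.shape), voi)
    sub = grid[voi.slices()]
    _, n = ndimage.label(sub, structure=ndimage.generate_binary_structure(3, 3))
    return MVDResult(
        method="vessel_count_3d",
        numerator=int(n),
        denominator=voi.n_voxels,
        voi=voi,
        params={"connectivity": 26},
    )


def mvd_voxel_fraction_3d(mask: BinaryVolume, voi: VOI) -> MVDResult:
    """Voxel-fraction metric: vessel voxels in the VOI per VOI voxel."""
    _check_frame(mask.shape, voi)
    numerator = int(mask.mask[voi.slices()].sum())
    return MVDResult(
        method="voxel_fraction_3d", numerator=numerator, denominator=voi.n_voxels, voi=voi
    )
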