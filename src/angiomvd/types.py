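"""Core value types shared by every stage of the pipeline.

Conventions, fixed once for the whole package:

* All grids are indexed ``(z, y, x)``, 0-based, with half-open ranges.
* Voxels are isotropic; the physical edge length is ``voxel_size_um``
  (default 9 µm, the working resolution of propagation-based phase-contrast
  micro-CT of small-animal vasculature). Anisotropic inputs are rejected,
  never resampled — every quantity downstream is a voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError

__all__ = ["VolumeImage", "BinaryVolume", "VOI", "Sinogram", "Skeleton"]

DEFAULT_VOXEL_SIZE_UM = 9.0


def _check_grid(data: np.ndarray, name: str) -> None:
    if data.ndim != 3:
        raise ValueError(f"{name} must be 3D (z, y, x); got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"{name} must have all dimensions >= 1; got shape {data.shape}")


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with isotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities; any float or integer dtype. Values must be finite.
    voxel_size_um : float
        Isotropic voxel edge length in microns (> 0).
    intensity_units : str
        Free-text tag, e.g. ``"reconstructed attenuation"`` or ``"arbitrary"``.
    """

    data: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    intensity_units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data, "VolumeImage.data")
        if not float(self.voxel_size_um) > 0:
            raise ValueError(f"voxel_size_um must be > 0; got {self.voxel_size_um}")
        self.voxel_size_um = float(self.voxel_size_um)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeImage.data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """A boolean vessel mask on the same grid conventions as :class:`VolumeImage`."""

    mask: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        _check_grid(arr, "BinaryVolume.mask")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("BinaryVolume.mask must be strictly two-valued")
            arr = arr.astype(bool)
        self.mask = arr
        if not float(self.voxel_size_um) > 0:
            raise ValueError(f"voxel_size_um must be > 0; got {self.voxel_size_um}")
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class VOI:
    """An axis-aligned cubic volume of interest.

    ``origin`` is the (z, y, x) corner, 0-based; the VOI spans the half-open
    box ``origin[i] <= index < origin[i] + shape[i]``. The default shape is
    100³ voxels, the region size over which the centerline density statistic
    is classically reported.
    """

    origin: tuple[int, int, int]
    shape: tuple[int, int, int] = (100, 100, 100)

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(int(v) for v in self.origin))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.shape) != 3:
            raise ValueError("VOI origin and shape must be integer triples")
        if any(o < 0 for o in self.origin):
            raise BoundsError(f"VOI origin must be >= 0; got {self.origin}")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"VOI shape must be positive; got {self.shape}")

    @property
    def n_voxels(self) -> int:
        z, y, x = self.shape
        return z * y * x

    @property
    def center(self) -> tuple[int, int, int]:
        return tuple(o + s // 2 for o, s in zip(self.origin, self.shape))  # type: ignore[return-value]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.shape))  # type: ignore[return-value]

    def check_within(self, parent_shape: tuple[int, int, int]) -> None:
        for axis, (o, s, p) in enumerate(zip(self.origin, self.shape, parent_shape)):
            if o + s > p:
                raise BoundsError(
                    f"VOI exceeds parent volume on axis {axis}: "
                    f"origin {o} + extent {s} > {p}"
                )


@dataclass
class Sinogram:
    """Parallel-beam projection data, one sinogram per z-slice.

    ``data`` is ``(n_slices, n_angles, n_detector_bins)``; ``angles_deg`` are
    strictly increasing in ``[0, 180)``.
    """

    data: np.ndarray
    angles_deg: np.ndarray
    detector_spacing_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        _check_grid(self.data, "Sinogram.data")
        if self.angles_deg.ndim != 1 or self.angles_deg.size < 2:
            raise ValueError("Sinogram needs at least 2 projection angles")
        if self.data.shape[1] != self.angles_deg.size:
            raise ValueError("Sinogram angle axis does not match angles_deg")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles_deg must be strictly increasing")
        if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 180:
            raise ValueError("angles_deg must lie in [0, 180)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Sinogram.data must be finite")
        self.detector_spacing_um = float(self.detector_spacing_um)


@dataclass
class Skeleton:
    """A 1-voxel-wide centerline set on a known source grid.

    Stored as a boolean volume of ``source_shape``; the voxel set and the
    endpoint/junction/branch graph are derived views (see
    :func:`angiomvd.skeleton.skeleton_to_graph`).
    """

    mask: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        _check_grid(arr, "Skeleton.mask")
        self.mask = arr.astype(bool)
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def source_shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def voxels(self) -> np.ndarray:
        """(N, 3) integer (z, y, x) coordinates of centerline voxels."""
        return np.argwhere(self.mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())
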