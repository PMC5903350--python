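"""Parallel-beam tomographic reconstruction.

A synchrotron beam is close enough to parallel that slice-by-slice 2D
filtered back projection (FBP) is the appropriate model: each z-slice of the
volume maps to one sinogram via the Radon transform, and FBP inverts it by
ramp-filtering every projection in the frequency domain and back-projecting
with linear interpolation, scaled by pi / (number of angles).

The forward projector exists so the reconstruction chain can be tested
end-to-end without beamline data. Both operators are linear. The region of
confidence of parallel-beam FBP is the inscribed circle of the slice;
values outside it are zero.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import iradon, radon

from .errors import GeometryError
from .types import Sinogram, VolumeImage

__all__ = ["forward_project", "fbp_reconstruct", "default_angles"]

FILTERS = {"ramlak": "ramp", "ramlak_hamming": "hamming"}


def default_angles(n: int = 900) -> np.ndarray:
    """``n`` uniform projection angles over [0, 180) degrees."""
    return np.linspace(0.0, 180.0, int(n), endpoint=False)


def forward_project(volume: VolumeImage, angles_deg) -> Sinogram:
    """Radon-transform every z-slice of ``volume`` at the given angles.

    Slices must be square; the detector has one bin per in-plane voxel, so
    the sinogram row at angle θ is the set of line integrals of the slice
    along rays perpendicular to direction θ. Mass outside the inscribed
    circle of the slice is ignored (it is outside the FBP region of
    confidence anyway).
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.ndim != 1 or angles.size < 2:
        raise GeometryError("forward projection needs at least 2 angles")
    nz, ny, nx = volume.shape
    if ny != nx:
        raise GeometryError(f"in-plane slices must be square; got {(ny, nx)}")
    data = np.empty((nz, angles.size, nx), dtype=float)
    for iz in range(nz):
        # skimage.radon returns (detector, angle); transpose to (angle, detector)
        data[iz] = radon(
            np.asarray(volume.data[iz], dtype=float), theta=angles, circle=True
        ).T
    return Sinogram(
        data=data, angles_deg=angles, detector_spacing_um=volume.voxel_size_um
    )


def fbp_reconstruct(sinogram: Sinogram, filter: str = "ramlak") -> VolumeImage:
    """Filtered back projection, slice by slice.

    ``filter`` is ``"ramlak"`` (pure ramp) or ``"ramlak_hamming"`` (ramp with
    Hamming apodization, trading resolution for noise suppression). The
    output in-plane size equals the detector bin count; voxels outside the
    inscribed circle are zero.
    """
    if filter not in FILTERS:
        raise GeometryError(f"unknown filter {filter!r}; expected one of {tuple(FILTERS)}")
    if sinogram.angles_deg.size < 2:
        raise GeometryError("reconstruction needs at least 2 angles")
    nz, _, ndet = sinogram.data.shape
    out = np.empty((nz, ndet, ndet), dtype=float)
    for iz in range(nz):
        out[iz] = iradon(
            sinogram.data[iz].T,
            theta=sinogram.angles_deg,
            filter_name=FILTERS[filter],
            interpolation="linear",
            circle=True,
            output_size=ndet,
        )
    return VolumeImage(
        data=out,
        voxel_size_um=sinogram.detector_spacing_um,
        intensity_units="reconstructed attenuation",
    )
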