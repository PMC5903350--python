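"""Volume I/O and VOI handling.

Supported on-disk formats:

* ``tiff_stack`` — one multi-page TIFF, one page per z-slice (tifffile).
* ``nifti`` — NIfTI-1 ``.nii``/``.nii.gz`` (nibabel); zooms carry the voxel
  size in microns and must be isotropic.
* ``raw`` — headerless little-endian raster in (z, y, x) order with a JSON
  sidecar ``<path>.json``: ``{"shape", "dtype", "voxel_size_um", "axis_order"}``.

Anisotropic headers are rejected (never resampled): every downstream
quantity is a voxel count, so resampling would silently change the statistic.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .errors import BoundsError, FormatError, SamplingError, UnsupportedMetadataError
from .types import DEFAULT_VOXEL_SIZE_UM, VOI, BinaryVolume, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "extract_voi",
    "sample_vois",
    "infer_format",
]

FORMATS = ("tiff_stack", "nifti", "raw")


def infer_format(path: str | Path) -> str:
    """Guess the volume format from a file extension."""
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if name.endswith(".raw"):
        return "raw"
    raise FormatError(f"cannot infer volume format from path {path!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_volume(
    path: str | Path,
    format: str | None = None,
    voxel_size_um: float | None = None,
) -> VolumeImage:
    """Read a 3D volume from disk.

    Parameters
    ----------
    path : path to the volume file.
    format : one of ``tiff_stack``, ``nifti``, ``raw``; inferred from the
        extension when omitted.
    voxel_size_um : overrides the voxel size from file metadata; when neither
        is available the default of 9 µm is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = format or infer_format(path)
    if fmt not in FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {FORMATS}")

    meta_vs: float | None = None
    if fmt == "tiff_stack":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            shaped = tif.shaped_metadata
            if shaped:
                meta_vs = shaped[0].get("voxel_size_um")
        if data.ndim == 2:
            data = data[None]
    elif fmt == "nifti":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-5):
            raise UnsupportedMetadataError(
                f"anisotropic voxel spacing in NIfTI header zooms={tuple(zooms)}; "
                "only isotropic volumes are supported (field: pixdim)"
            )
        meta_vs = float(zooms[0]) if zooms[0] > 0 else None
        # nibabel arrays are (x, y, z); transpose to the package's (z, y, x).
        data = np.asanyarray(img.dataobj).T
    else:  # raw
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"raw volume requires JSON sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        for key in ("shape", "dtype"):
            if key not in meta:
                raise FormatError(f"raw sidecar missing required field {key!r}")
        if meta.get("axis_order", "zyx") != "zyx":
            raise UnsupportedMetadataError(
                f"unsupported axis_order {meta['axis_order']!r} (field: axis_order)"
            )
        shape = tuple(int(v) for v in meta["shape"])
        dtype = np.dtype(meta["dtype"])
        raw = np.fromfile(path, dtype=dtype)
        expected = int(np.prod(shape))
        if raw.size != expected:
            raise FormatError(
                f"raw file holds {raw.size} values but sidecar declares "
                f"shape {shape} ({expected} values)"
            )
        data = raw.reshape(shape)
        meta_vs = meta.get("voxel_size_um")

    vs = voxel_size_um if voxel_size_um is not None else (meta_vs or DEFAULT_VOXEL_SIZE_UM)
    return VolumeImage(data=data, voxel_size_um=vs)


def write_volume(volume: VolumeImage, path: str | Path, format: str | None = None) -> None:
    """Write a volume to disk, losslessly for supported dtypes."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    fmt = format or infer_format(path)
    if fmt not in FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {FORMATS}")

    if fmt == "tiff_stack":
        tifffile.imwrite(
            path,
            volume.data,
            photometric="minisblack",
            metadata={"voxel_size_um": volume.voxel_size_um},
        )
    elif fmt == "nifti":
        vs = volume.voxel_size_um
        affine = np.diag([vs, vs, vs, 1.0])
        # store (x, y, z) as NIfTI expects; read_volume transposes back
        img = nib.Nifti1Image(np.ascontiguousarray(volume.data.T), affine)
        img.header.set_zooms((vs, vs, vs))
        nib.save(img, str(path))
    else:  # raw
        arr = np.ascontiguousarray(volume.data)
        arr.tofile(path)
        sidecar = {
            "shape": list(arr.shape),
            "dtype": arr.dtype.name,
            "voxel_size_um": volume.voxel_size_um,
            "axis_order": "zyx",
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def extract_voi(volume: VolumeImage | BinaryVolume, voi: VOI):
    """Crop a VOI out of a volume (or mask); returns the same type as the input.

    The VOI must lie fully inside the parent volume — out-of-bounds requests
    raise :class:`BoundsError` rather than clipping silently.
    """
    voi.check_within(volume.shape)
    sl = voi.slices()
    if isinstance(volume, BinaryVolume):
        return BinaryVolume(mask=volume.mask[sl].copy(), voxel_size_um=volume.voxel_size_um)
    return VolumeImage(
        data=volume.data[sl].copy(),
        voxel_size_um=volume.voxel_size_um,
        intensity_units=volume.intensity_units,
    )


def sample_vois(
    volume_shape: tuple[int, int, int],
    n: int,
    shape: tuple[int, int, int] = (100, 100, 100),
    seed: int | None = None,
    region_mask: BinaryVolume | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[VOI]:
    """Sample ``n`` in-bounds VOIs uniformly over valid placements.

    A placement is valid when the VOI fits inside ``volume_shape`` and, if
    ``region_mask`` is given, its center voxel lies in the mask. Sampling is
    uniform without replacement over center voxels, so returned VOIs are
    distinct but may overlap. Deterministic for a fixed ``seed``.
    """
    if n < 1:
        raise SamplingError(f"n must be >= 1; got {n}")
    volume_shape = tuple(int(v) for v in volume_shape)
    shape = tuple(int(v) for v in shape)
    maxo = [p - s for p, s in zip(volume_shape, shape)]
    if any(m < 0 for m in maxo):
        raise SamplingError(
            f"VOI shape {shape} does not fit in volume of shape {volume_shape}"
        )
    # valid center voxels form the box [s//2, s//2 + maxo] per axis
    lo = [s // 2 for s in shape]
    counts = [m + 1 for m in maxo]

    if region_mask is not None:
        mask = region_mask.mask if isinstance(region_mask, BinaryVolume) else np.asarray(region_mask, bool)
        if mask.shape != volume_shape:
            raise SamplingError("region_mask shape must equal volume_shape")
        sub = mask[tuple(slice(l, l + c) for l, c in zip(lo, counts))]
        flat_valid = np.flatnonzero(sub.ravel())
    else:
        flat_valid = None

    n_valid = int(np.prod(counts)) if flat_valid is None else flat_valid.size
    if n_valid < n:
        raise SamplingError(
            f"only {n_valid} valid VOI placements exist; {n} requested"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    pick = rng.choice(n_valid, size=n, replace=False)
    flat = pick if flat_valid is None else flat_valid[pick]
    zi, yi, xi = np.unravel_index(flat, counts)
    return [
        VOI(origin=(int(z), int(y), int(x)), shape=shape)
        for z, y, x in zip(zi, yi, xi)
    ]
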