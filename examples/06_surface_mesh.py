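"""Export a triangle mesh of the segmented vasculature for 3D viewing."""

import tempfile
from pathlib import Path

from angiomvd import make_group_phantoms, marching_cubes, write_mesh

phantom = make_group_phantoms("normal", n_samples=1, seed=3)[0]
mesh = marching_cubes(phantom.mask_truth)

print(f"vertices: {mesh.n_vertices}, faces: {mesh.n_faces}")
print(f"enclosed volume: {mesh.enclosed_volume_um3():.3e} um^3")
print(f"voxel volume:    {phantom.mask_truth.mask.sum() * 9.0 ** 3:.3e} um^3")

out = Path(tempfile.mkdtemp()) / "vessels.ply"
write_mesh(mesh, out, format="ply_ascii")
print(f"wrote {out} — open it in any mesh viewer (MeshLab, ParaView, ...)")
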