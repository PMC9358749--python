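"""Generate the synthetic study inputs: phantom surfaces, CT-like volumes,
landmark template, and the simulated 13 x 4 digitization study.

Writes the landmark table (text) under results/phantom/ and the binary
artifacts (STL mesh, MetaImage volume) under scratch/phantom/.  Everything
is seeded; re-running reproduces the files byte-identically.
"""

import pathlib

from surfmorph import PhantomSpec, StudySimSpec, phantom
from surfmorph.gm import write_landmark_table
from surfmorph.mesh import write_stl
from surfmorph.volseg import write_mhd

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "phantom"
BIN = ROOT / "scratch" / "phantom"
OUT.mkdir(parents=True, exist_ok=True)
BIN.mkdir(parents=True, exist_ok=True)

# Desk-scale phantom: anatomical radius and flares, shortened shaft so the
# CT-like volume stays small; acquisition emulates 0.625 mm isotropic voxels.
spec = PhantomSpec(shaft_length=60.0, mesh_resolution=1.2, seed=1)

mesh = phantom.generate_phantom_mesh(spec)
write_stl(mesh, BIN / "phantom_reference.stl")
print(
    f"phantom mesh: {mesh.n_vertices} vertices, {mesh.n_faces} faces, "
    f"closed={mesh.is_closed()}, volume={mesh.volume():.1f} mm^3"
)

vol = phantom.voxelize_phantom(mesh, 0.625, psf_sigma=0.4, noise_sd=30.0, seed=2)
write_mhd(vol, BIN / "phantom_ct.mhd")
print(f"CT-like volume: shape={vol.shape}, spacing={vol.spacing} mm")

template = phantom.define_phantom_template(spec)
print(
    f"template: {template.n_points} points "
    f"({(template.epiphysis == 'proximal').sum()} proximal, "
    f"{(template.epiphysis == 'distal').sum()} distal)"
)

sim = StudySimSpec(n_specimens=13, seed=7)
configs = phantom.simulate_landmark_study(template, sim)
write_landmark_table(configs, template, OUT / "landmark_study.tsv")
print(f"simulated study: {len(configs)} configurations -> {OUT / 'landmark_study.tsv'}")
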