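"""3D occupancy density of lipid head-group pseudo-particles.

30% of the particles concentrate in a Gaussian hotspot (sigma = 5 A); the
rest are uniform over a bilayer-like slab, at a 2:1 PC:PG composition.
The density grid is normalized by frame count, so its values are mean
per-frame occupancies, and its peak localizes the hotspot.
"""

import numpy as np

import gatescope as gs

center = np.array([10.0, -5.0, 0.0])
traj = gs.make_lipid_field(
    1000, gs.SynthSpec(seed=11, n_frames=500, n_replicas=1),
    hotspot=(center, 5.0, 0.3),
)[0]

grid = gs.density_grid(
    traj, particle_selection="name P", spacing=2.0,
    extent=(np.array([-40.0, -40.0, -20.0]), np.array([40.0, 40.0, 20.0])),
)
peak_idx = np.unravel_index(np.argmax(grid.values), grid.values.shape)
peak = grid.voxel_center(peak_idx)

print(f"grid shape {grid.shape}, spacing {grid.spacing} A")
print(f"total mean per-frame in-grid count: {grid.values.sum():.1f} "
      f"({traj.n_atoms} particles)")
print(f"density peak at {np.round(peak, 1)} A; programmed hotspot center "
      f"{center} (error {np.linalg.norm(peak - center):.2f} A)")

gs.write_dx(grid, "lipid_density.dx")
print("wrote lipid_density.dx (OpenDX) for 3D viewers; in a real system "
      "such grids reveal lipid-class enrichment around a membrane protein.")
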