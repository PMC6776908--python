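"""Free-energy landscape of a two-state system.

Generates five replicas of a trajectory hopping between two conformational
basins (80% / 20% occupancy) along a collective mode, runs Cartesian PCA
on the pooled frames, Boltzmann-inverts the 2D projection histogram, and
reads off the basin free-energy difference.  The expected value is
-RT ln(0.2/0.8) = 0.826 kcal/mol at 300 K.
"""

import numpy as np

import gatescope as gs

ref = gs.make_ideal_helix(20)
mode = gs.make_collective_mode(ref, seed=42)
trajs, _ = gs.make_two_state_trajectory(
    ref, mode, separation=6.0, p_major=0.8, noise_sigma=0.5,
    spec=gs.SynthSpec(seed=42, n_frames=2000, n_replicas=5),
)

model = gs.fit_pca(trajs, fit_selection="all", analysis_selection="all")
projections = np.concatenate([gs.project(t, model) for t in trajs])
fel = gs.landscape(projections, bins=40, temperature=300.0)

per_replica = [gs.basin_delta_g(gs.project(t, model)[:, 0]) for t in trajs]
rep, frame = gs.representative_conformation(trajs, model, fel)

print(f"PC1+PC2 explained variance: {model.explained_fraction[:2].sum():.1%}")
print(f"basin dG per replica (kcal/mol): {np.round(per_replica, 3)}")
print(f"mean basin dG: {np.mean(per_replica):.3f} kcal/mol "
      f"(closed form 0.826)")
print(f"representative conformation: replica {rep}, frame {frame}")
print("The basin dG is the Boltzmann-inverted population ratio of the two "
      "states; the representative frame sits in the most populated bin.")
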