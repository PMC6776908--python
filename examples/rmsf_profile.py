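"""Per-residue RMSF from replicas of a harmonic trajectory.

Atoms fluctuate isotropically with per-axis sigma = 1.0 A, so the true
all-atom RMSF is sigma * sqrt(3) = 1.732 A.  Frames are superposed onto
the converged average structure before measuring, exactly as one would
for a membrane-protein trajectory.
"""

import numpy as np

import gatescope as gs

ref = gs.make_ideal_helix(30)
trajs = gs.make_harmonic_trajectory(
    ref, sigma=1.0, spec=gs.SynthSpec(seed=7, n_frames=1000, n_replicas=5)
)

profiles = [gs.rmsf(t, fit_selection="all", analysis_selection="all")
            for t in trajs]
pooled, sem = gs.pool_rmsf(profiles)

print(f"replica-mean RMSF over {len(pooled.residue_keys)} residues:")
print(f"  min {pooled.residue_rmsf.min():.3f}  "
      f"max {pooled.residue_rmsf.max():.3f}  "
      f"mean {pooled.residue_rmsf.mean():.3f} A   (true value 1.732 A)")
print(f"  per-residue SEM over 5 replicas: {sem.mean():.4f} A")
print("RMSF measures per-atom mobility about the mean structure; flexible "
      "loops in real proteins stand out as peaks over the rigid helices.")
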