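# Methods

This note records the models, conventions, numerical choices, and
limitations behind the gatescope analyses.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and formats

Structures are ordered atom lists with chain, residue number (author
numbering preserved, never renumbered), atom name, element, and mass
(from a fixed internal table of standard atomic weights; element inferred
from the atom name per PDB v3.3 justification when the element column is
blank).  Trajectories are a topology plus an F × N × 3 coordinate array;
the frame spacing (default 200 ps, the saving interval emulated by the
generators) is metadata only — no analysis here depends on time
correlation.

Multi-model PDB is the required trajectory dialect; plain per-frame XYZ
text is the lightweight alternative.  The PDB reader is a strict
fixed-column parser that reports the line number of a malformed
coordinate field and the frame index of a topology mismatch; write→read
round trips preserve atom order, identifiers, and coordinates to the
0.001 Å column precision (cross-checked against gemmi in the test suite).
Binary formats (DCD/XTC) are deliberately out of scope.  Tabular output
is TSV with `#` comment headers; volumetric output is OpenDX text
(written and read through GridDataFormats); empty-bin free energies are
serialized as the token `inf`, never a number.

Selections use a small deterministic expression language (`chain`,
`resid a-b`, `name n1,n2`, `backbone` = N/CA/C/O, `calpha`, `heavy` =
non-hydrogen, `all`, with `and`/`or`/`not` and parentheses).  Hydrogens
are retained when present; `heavy` excludes them, and "all-atom" analyses
default to heavy atoms since deposited models usually lack hydrogens
while MD-derived ones carry them.

## Superposition

Rigid fits use the SVD solution of the weighted least-squares problem
with a determinant sign guard so the returned rotation is always proper
(det = +1); reflections are never accepted, even for near-planar fit
sets.  Fitting is unweighted over the selected atoms by default (the
common convention for coordinate RMSD fitting); mass weighting is an
option.  Collinear or rank-deficient fit sets raise a degeneracy error.
Frame stacks are fitted with a batched SVD that is numerically identical
to the per-frame path.

The average structure is computed iteratively: fit all frames to the
current average over the fit selection, recompute the mean, and stop when
the mean per-atom coordinate change drops below 1e-6 Å (default) or
after 50 iterations (warning logged, last average returned).  This
average is the default reference for RMSF and PCA superposition; a
single-pass fit to frame 0 is available where speed matters.

Displacement fields between two states match residues by (chain, residue
number) through an explicit chain map; no sequence alignment is
performed, since the intended use is comparing entries of the same
protein.  Vectors are Cα positions of state B (after fitting on the
chosen selection) minus state A; residues missing from either state are
skipped and logged.

## Gate geometry

Turn centers of mass are mass-weighted (not geometric), over all atoms of
the four consecutive residues by default (backbone or Cα classes are
options).  Helix axis vectors run from the backbone COM of the first four
residues to that of the last four, following residue order (N→C).  The
inter-helix angle η is the arccos of the axis dot product, in [0°, 180°];
helix or hairpin tilt against a normal is folded into [0°, 90°].  A
hairpin axis is (v₁ − v₂)/|v₁ − v₂| for its two (antiparallel) helices; a
near-parallel pair declared as a hairpin is an error rather than a
near-zero axis.

For structures without membrane atoms the membrane normal is estimated as
the first principal axis of the Cα spread of a declared transmembrane
bundle — TM helices run roughly along the normal, so their pooled Cα
variance is largest along it.  The sign is left to the caller (chain
map / leaflet knowledge).  The estimate degrades when the bundle is wide
relative to helix length; the synthetic construct used in tests keeps the
ring narrow for exactly this reason, and on real entries the convention
should be checked against an independent orientation (e.g., OPM-style).

The inter-state tilt of one helix is measured by superposing state B onto
state A over the Cα atoms of a fit selection that excludes the moving
elements, then taking the angle between the helix's axis vectors in the
two aligned states.  This isolates the helix's own reorientation from
both global motion and normal-estimation bias.

Residue quadruplets for turn-COM distances and helix ranges are
configuration inputs, not hard-coded: the figure-level definitions of
specific distance pairs are tied to one protein's numbering, and baking
them in would just invent residue numbers.

Per-replica series are summarized as histograms of relative frequencies
(each replica's frequencies sum to 1) on 50 shared bins spanning the
pooled min–max range padded 2% (configurable), with the mean and the
standard error of the mean (sd/√n, ddof = 1) per bin over replicas, and
the frame-0 "starting structure" value reported alongside.

## RMSF

RMSF_i = sqrt(mean_f |r_i(f) − ⟨r_i⟩|²) per analysis atom after
superposition on the fit selection; residue values are arithmetic means
over the residue's analysed atoms; replica aggregation is mean ± SEM.
Superposition removes six rigid degrees of freedom, so for isotropic
noise the expected RMSF is deflated by sqrt((3N−6)/3N) relative to σ√3 —
negligible for hundreds of atoms, visible for tiny test systems; the test
suite accounts for it explicitly where it matters.

## PCA and the free-energy landscape

Frames of all replicas are pooled, superposed on the fit selection to the
overall average, and the covariance of the analysis atoms' Cartesian
coordinates is eigendecomposed via SVD of the centered data matrix
(eigenvalues = s²/F; identical to the covariance eigenproblem but better
conditioned).  Analysis coordinates default to Cα atoms, keeping the
covariance well-conditioned at desk scale; all-heavy-atom analysis is an
option.  Each eigenvector's largest-magnitude component is made positive
so projections are reproducible across runs.  Eigenvalues are sorted
descending; explained fractions are eigenvalue/trace.

Projections of the pooled frames onto (PC1, PC2) are binned on a
100 × 100 grid over the 2%-padded data range by default (binning is
exposed: absolute ΔG readouts depend on it, and coarser grids are
appropriate for smaller frame counts).  ΔG_conf,i = −RT ln(N_i/N_max)
with R = 1.9872036 × 10⁻³ kcal mol⁻¹ K⁻¹ and T = 300 K by default;
kcal/mol throughout.  The most populated bin is exactly 0; unoccupied
bins are +inf.  Locating an external conformation superposes and projects
it like a frame; a projection outside the landscape is flagged and the
nearest bin's value reported.  The representative conformation is the
frame whose projection is nearest the center of the most populated bin
(ties broken by lowest replica, then frame — fully deterministic).
Displacement ("porcupine") vectors along a component are the
eigenvector's per-atom 3-vectors scaled by scale·√eigenvalue (the mode's
RMS amplitude), with arrows below a magnitude cutoff omitted.

For two-state systems, `basin_delta_g` splits PC1 coordinates with a 1D
two-means threshold and returns −RT ln(n_minor/n_major); it assumes a
clearly bimodal projection.

## Lipid densities

Frames are superposed on the protein fit selection (to its average
conformation) before the selected particles are binned on a regular grid
(default spacing 1.0 Å; default extent the fitted protein's bounding box
padded 15 Å).  Voxel values are occupancy counts divided by the frame
count — mean per-frame occupancy, with no voxel-volume or bulk-density
normalization — so replicating frames leaves the grid exactly unchanged
and grids over equal frame counts are directly comparable.  Particles
outside the extent are counted and logged, never an error.  Head-group
classes are selection expressions supplied by the caller; no lipid
template library is embedded.

## Synthetic data

The generators define the validation conditions and are first-class,
tested code:

* **Ideal helices** place backbone pseudo-atoms (N, CA, C, O) on the
  canonical α-helix parameterization (rise 1.5 Å, twist 100°, Cα radius
  2.3 Å; the other atoms at standard cylinder radii and wheel-phase
  offsets).  Axis recovery by the terminal-turn construction is accurate
  to < 1° at 20 residues; at 22 residues the terminal-turn phases realign
  and the bias vanishes, which the geometry fixtures exploit.
* **Harmonic trajectories** add isotropic per-atom Gaussian noise
  (per-axis σ) to a reference, optionally with injected random rigid
  motions per frame; the true RMSF is σ√3.
* **Two-state trajectories** hop between a reference basin and one
  displaced by separation·mode with major-basin probability p, storing
  the true basin labels as a side channel; separations below 4× the noise
  σ trigger a merge warning.  Collective modes are generated orthogonal
  to the six rigid-body motions of the reference, because superposition
  removes exactly that subspace — a mode with rigid components would be
  partially (and correctly) absorbed by fitting.
* **Gate toys** pose two copies of one template helix with prescribed
  per-frame inter-axis angles and turn-COM distances.  Because both
  helices share the template, the axis-estimation bias rotates with each
  pose and cancels: programmed angles and distances are recovered to
  floating-point accuracy.
* **Lipid fields** draw head-group pseudo-particles per frame, uniform
  over a slab plus an optional Gaussian hotspot fraction, with class
  labels split 2:1 PC:PG by default (the emulated bilayer composition).
* **The translocon-like construct** (`make_translocon_toy`) is a purely
  synthetic stand-in, not a deposited structure: a ten-helix bundle with
  an accessory hairpin, built in two states with a programmed hairpin
  tilt (30°), inter-state tilt of one gate helix (5°), and rigid shift of
  another (5 Å), with lower-cased chain ids in the second state to
  exercise chain-map correspondence.

Defaults mirror the emulated production regime: 5 replicas, 200 ps frame
spacing, 5,000 frames per replica at full scale (tests and the acceptance
script use 800–5,000 frames per stage, chosen as the smallest sizes at
which the statistical bounds above are meaningful).  Each replica draws
from its own substream spawned from the master seed, so replica sets are
bit-reproducible independently.  Noise is time-uncorrelated by design
(no Ornstein–Uhlenbeck dynamics): none of the implemented analyses
depends on frame autocorrelation.

What passing these tests does and does not show: the generators have
exact, known statistical structure, so the tests validate the estimators
(superposition, RMSF, PCA, Boltzmann inversion, density normalization,
geometry operators) — they do not validate force fields, sampling
convergence, or any property of real bilayer dynamics, and absolute
free-energy readouts on real data remain binning-dependent.

## Pipeline and reproducibility

A run is one YAML config (seed, input or synth block, stage options,
output directory).  Stages execute in dependency order; every output
carries a provenance header (package version, config hash, seed); errors
abort with the stage name and a machine-readable code.  Deterministic
stages are byte-reproducible under a fixed config (modulo the provenance
hash when the output path changes); stochastic stages are reproducible
under a fixed seed.

## Known limitations

* No mmCIF parsing, bond perception, or periodic-boundary handling (the
  intended systems are analyzed as non-periodic).
* Correspondence between entries is by residue number through a chain
  map; diverged sequences would need an alignment step that is out of
  scope.
* The membrane-normal convention is a principal-axis estimate, not a
  bilayer fit; absolute tilt values inherit its bias (inter-state tilts
  do not, by construction).
* Absolute landscape ΔG values depend on bin geometry and frame counts;
  only closed-form and relative quantities are asserted.
* Secondary structure is declared, never detected.
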