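# Methods

This note records the models, conventions and numerical choices behind
`mdshift`, and what the synthetic benchmarks do and do not demonstrate.

## Containers and conventions

Coordinates are Angstrom throughout; residue numbering is 1-based author
numbering and never renumbered. A `Structure` is a fixed atom topology plus
one coordinate set; a `Trajectory` is an (F, N, 3) frame array over that
topology with an optional `time_per_frame` (ns). Frame windows are
inclusive 0-based index pairs; time windows are converted by dividing by
`time_per_frame` and rounding down, i.e. half-open on time but inclusive on
frames. Multi-model PDB is the only trajectory interchange format: it is
plain text and diffable, which we value over compactness for ensemble
fixtures; binary dialects are out of scope. Alternate locations: the first
altloc is kept, others dropped. Calpha atoms are identified by atom name
`"CA"` exactly. Van der Waals radii come from a bundled Bondi-style element
table; unknown elements fall back to 1.5 Å with a warning. Pseudo-atoms may
override the radius in memory, but PDB has no radius column, so
element-table radii apply after any write/read round trip.

## Superposition

`kabsch` minimizes weighted RMSD over proper rotations + translations via
SVD of the weighted cross-covariance, with the usual determinant correction
restricting the solution to SO(3) (chirality is never flipped). Weights
default to uniform. Fewer than 3 points is an error. Rank-deficient
configurations (collinear point sets) are *not* an error: the SVD solution
still attains the global minimum RMSD there, only the rotation is
non-unique, so the routine warns and returns a valid optimum. (Per-atom
distances to a collinear target are invariant across the solution family,
so shift distances against straight reference chains remain well defined.)
Whole-trajectory fits are batched (vectorized 3x3 SVDs), which keeps
2000-frame fits in the millisecond range.

The default fit selection is all Calpha; "backbone" for RMSD reporting
means {N, CA, C, O} and both are configurable, since conventions differ
between studies.

## RMSF

RMSF is computed about each atom's own time-mean position after fitting
every frame to the reference — the standard definition; fluctuation about
the reference position is a different (larger) quantity and is not used.
Replicate averaging is the arithmetic mean of per-replicate profiles
aligned by residue number, not a pooled-frame RMSF, so replicates weigh
equally regardless of length.

One bias worth knowing: the per-frame rigid-body fit absorbs 6 of the 3N
noise degrees of freedom, shrinking measured RMSF by a factor of about
sqrt(1 − 2/N). For a 310-residue chain this is 0.3% and irrelevant; for toy
chains of a few dozen residues it is visible, which is why the closed-form
benchmarks use long chains.

## Average structures and shift maps

Average structures are coordinate-wise means of frames fitted to the
reference over an explicit window. Because each frame's fit depends on its
noise, the "average equals arithmetic frame mean" identity holds exactly
only when the optimal fit is the identity (static frames, pure-translation
perturbations); with noise the discrepancy is second order and tested at
tight tolerance rather than bitwise.

Shift distances overlay condition B's average structure onto condition A's
over *all* selected Calpha (not a subset), then take per-Calpha distances.
The [0, 1] mapping is rank-based: with k = floor(N/2) largest distances
saturated at 1, the remaining m are sorted ascending and the i-th smallest
(1-based) gets (i − 1)/m. "Ordered then linearly mapped" admits a
value-linear reading too; both coincide for evenly spaced distances, and
the value-linear variant is available as `variant="minmax"`, mapping
unsaturated distances linearly between the smallest unsaturated distance
and the saturation threshold, with boundary ties clipped just below 1.
Rank-based is the default because it is scale-free and keeps the
saturated group uniquely identifiable (value exactly 1; unsaturated values
live in [0, 1)). Odd N under-saturates (k = floor(N/2)); ties at the
saturation boundary are resolved stably by residue order.

## Distance tracks and cavity volumes

Pair distances are computed on raw frames — inter-atomic distances are
rigid-motion invariant, so superposing first would only add noise. Window
means are arithmetic over inclusive frame ranges; the between-condition
delta is mean(B) − mean(A), averaged over replicates.

The cavity estimator is a grid flood fill, chosen over alpha-shape pocket
construction because it is deterministic and checkable against analytic
oracles. Defaults: grid spacing 0.25 Å, probe radius 1.4 Å (a water-sized
probe), 6-connectivity. The convex-hull clip over the lining atoms bounds
the pocket against open solvent; the seed point selects the connected void.
Degenerate inputs are rejected (seed inside an atom sphere, < 4 or coplanar
lining atoms); a seed outside the hull yields an empty volume with a
warning rather than an error. Discretization error is confined to boundary
voxels (|ΔV| ≤ surface_voxels × spacing³, verified on spherical cages);
both rotation invariance and spacing refinement are tested against that
bound. Volumes from this estimator are meaningful *relative to each other*
at fixed settings; no parity with alpha-shape tools' absolute numbers is
claimed. Pocket lining residues and analysis windows are always explicit
user configuration — the tool does not detect pockets or infer windows.

## Synthetic ensembles

The generator produces Calpha-only toy chains ("helix": ideal alpha-helix
trace, 100° turn and 1.5 Å rise per residue; or "line"), both with 3.8 Å
consecutive-Calpha spacing, plus optionally a rigid spherical cage of
pseudo-atoms enclosing an empty cavity of declared radius. Frame t is

    base + event_ramp(t) · offset + Gaussian(0, σ_residue per axis)

followed, when global motion is on, by a uniform random SO(3) rotation
(normalized Gaussian quaternions) and a Gaussian translation (σ = 3 Å per
axis) of the whole frame. Noise is drawn independently per frame — the
simplest process with the features the analysis probes; autocorrelated
dynamics are deliberately out of scope. The displacement event is a linear
ramp across its frame window, then held. Replicate r uses seed + r; local
noise and global motion use separate, independently derived RNG streams so
that toggling global motion never changes the local draws (this underlies
the invariance tests). Same spec + seed reproduces output bytes exactly.

`paired_experiment` generates two conditions and a manifest of their
declared differences (flexibility-window multipliers, displacement events,
cavity radii) for recovery testing.

### The `two_state_kinase` preset

The packaged study conditions: a 310-residue helical chain, base σ =
0.25 Å/axis, two replicates × 2000 frames (1.5 ns/frame of nominal time),
global motion on, and a pocket cage of 350 atoms at 8 Å shell radius.
Condition "unphos" elevates flexibility at residues 118–125 (×3) and
203–211 (×4) and has a 5 Å cavity; "phos" halves those multipliers (×1.5,
×2), adds a −2 Å displacement of residues 57–63 toward residue 195 ramped
over frames 900–1900, and contracts the cavity to 4 Å. Analysis windows:
average structures over frames 1000–1999, pair window and pocket window
900–1900, pocket grid 0.25 Å at probe 0. Verdict tolerances: 0.05 Å (RMSF
window mean), 0.2 Å (distance), 10 ų (volume); deltas inside tolerance
flag "none". These sizes keep a full comparison around 4 s on one CPU
while leaving every injected effect an order of magnitude above its
sampling noise. A miniature `smoke` preset (30 residues, 120 frames)
exists for plumbing checks only.

### What passing does and does not show

The generator has isotropic, uncorrelated, Gaussian local noise, a rigid
pocket, and exactly the injected differences. Real MD ensembles have
anisotropic correlated fluctuations, solvent, conformational substates and
drifting pockets. Green benchmarks therefore certify the *analysis
machinery* — that superposition, averaging, mapping and volume estimation
recover known inputs at known noise — not that any particular biological
effect would be detectable in real trajectories.

## Pipeline

`run_compare` executes generate/read → RMSD series → per-replicate RMSF →
replicate average → windowed average structures → shift map → distance
tracks + window deltas → cavity volumes, then derives verdict flags, each
backed by a numeric delta in the serialized report. Between-condition
average structures are pooled over replicates (mean of per-replicate
averages with equal frame counts). Single stages (`run_stage`) reuse the
same artifact-producing code paths, so their TSV/PDB outputs are
byte-identical to the corresponding slice of a full run; floats in TSVs are
fixed at 6 decimals for that reason. Condition labels are free strings —
"unphos"/"phos" appear only in the preset; the tool is not specific to any
one protein.

## Known limitations

- Atom correspondence across conditions is by topology order and residue
  number; no sequence alignment is performed.
- No statistical significance testing between conditions; verdicts are
  point comparisons against explicit tolerances.
- Mass-weighted RMSF, PCA/mode decompositions, mmCIF and binary trajectory
  formats are out of scope.
- Pseudo-atom vdW overrides do not survive PDB round trips (no radius
  column in the format).
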