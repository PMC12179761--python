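# Methods

This note records the models, conventions and numerical choices behind
shellpick, in the order the pipeline applies them.  Nothing here states a
result; every number quoted as an outcome is computed by the test suite
or by `scripts/acceptance.py`.

## Scope and assumptions

shellpick analyzes *configurations*, not dynamics: every stage (shell
extraction, reduction, covariance analysis, basin weighting) consumes an
ordered set of frames and never uses time information beyond frame order
(which only the convergence check exploits, by splitting contiguously).
The solute is treated as a single molecule; multi-residue solutes
(peptides, chains) are collapsed into one rigid body for the purpose of
the solute/solvent partition.  The solvent must be homogeneous (one
species); mixed solvents are out of scope.  Trajectory coordinates are
Angstrom internally; GRO files are converted from nm on read/write.

## Shell extraction (ellipsoid method)

The ellipsoid is recomputed per frame from that frame's solute
coordinates: center = geometric center, axes = gyration-tensor
eigenvectors, semi-axes = `scale · √λ` (descending), expanded by a common
factor so every solute atom satisfies the unpadded metric ≤ 1, then
padded.  Parameters:

- `padding` (Å, default 3.0): one hydration-shell radius; the padded
  semi-axes enter the in/out metric.  Degenerate directions (zero
  eigenvalue — planar or linear solutes) fall back to the padding alone,
  so a single atom yields a sphere of radius `padding`.
- `scale` (dimensionless, default 1.0): with the enclosure expansion the
  default means "the bare ellipsoid just encloses the solute".
- Solvent reference point: molecule center of geometry by default
  (`nearest_atom` optional).  Whole molecules are kept or discarded,
  never split.
- M is fixed across frames (a covariance analysis needs fixed
  composition): the floor of a statistic (median by default; mode and min
  available) of the per-frame in-ellipsoid counts, clamped to ≥ 1.
- Slots are ordered by ascending metric, ties toward the lower molecule
  id — solvent molecules are interchangeable, so a deterministic
  relabeling is mandatory before any per-slot statistics.
- With a periodic box, each solvent molecule is rigidly shifted to the
  image whose center is nearest the ellipsoid center (orthorhombic
  minimum image) before the metric is evaluated.

## Reduction to bound solvent

Aggregation centers generalize the uniform "n solvent molecules at each
of l atoms" to per-center quotas nᵢ (k = Σ nᵢ), because real usage is
asymmetric — e.g. four waters at a carboxylate and three at an ammonium.
Distances are `nearest_atom` by default (min over center-atom/solvent-atom
pairs; hydrogen-bond geometry is atom-pairwise) with a `com` mode
available.  Conflicts (one molecule nearest to two centers) are resolved
by a single global greedy pass over all (center, solvent) pairs sorted by
ascending distance (ties: center order as given, then solvent index);
each molecule serves at most one center — the assignment is disjoint.
Within a center, slot order is the order of assignment, i.e. ascending
distance.  A center that cannot fill its quota raises an error naming the
frame rather than silently shrinking k.  `suggest_centers` offers
advisory candidates (N/O/S atoms grouped by a 1.8 Å heavy-atom bond
heuristic when coordinates are available); quotas are a chemical
judgement left to the user.

## Superposition and essential dynamics

Kabsch superposition with proper rotations only (determinant +1 enforced
through the SVD sign correction), batched over frames.  The fit subset
defaults to the solute atoms: in the frozen-solute protocol this places
every frame in the solute body frame and the solvent slots carry all the
fluctuation.  Unit fit weights by default; mass weighting is a flag, not
the default, since classic ED operates on plain Cartesian coordinates.
The reference defaults to the first frame; an iterated mean reference
(two fit–average passes) is available.  Degenerate fit subsets (< 3
atoms, collinear) are rejected.

Covariance uses the population (1/N) normalization so that eigenvalue v
equals the variance of the projections on eigenvector v *exactly*, and
Parseval's identity (Σ projections² = squared deviation from the mean,
per frame) holds to rounding.  Eigenvalues below 1e-12 Å² are clipped to
zero.  Eigenvector sign is fixed by making the largest-magnitude
component positive, so results are reproducible across eigensolvers.
`ed_analyze(..., superpose=False)` skips the fit for input already in a
body frame.  Projecting an external structure replays the stored fit
(reference + fit subset) when `prefit=True`, which reproduces the stored
projections of analyzed frames exactly; `prefit=False` dots directly and
is the right choice for structures already expressed in the fitted frame
(the mean, or mean + t·eigenvector).

## Free-energy landscapes and basins

ΔG(bin) = −ln(count/count_max) in kT units (the standard Boltzmann
inversion; the declared temperature only matters if converting out of kT).
Histogram range is the data range expanded by 5%; `n_bins` defaults to
64 per dimension.  As a rule of thumb the expected count in an occupied
bin should be ≳ 10, so analyses of short blocks should reduce `n_bins`
accordingly (the bundled small-scale tests use 8–24 bins for 200–500
frame blocks).  Empty bins carry a finite cap (max occupied ΔG + 1),
never an infinity.

Basin detection is steepest descent on the bin grid (8-neighborhood in
2-D, ±1 in 1-D) over occupied bins with ΔG ≤ `g_cut` (default 4 kT);
plateau ties break toward the lower flat bin index.  Three merge rules
then apply, in order:

1. **Shallow saddles.**  A basin whose depth below its lowest connecting
   saddle (min over adjacent cross-basin bin pairs of the larger ΔG) is
   smaller than `min_depth` (default 1 kT) merges across that saddle,
   into the deeper of the two.
2. **Isolated speckle.**  A basin with no eligible-bin connection to any
   other can only be left at the cutoff level, so its effective saddle
   is `g_cut`; if that leaves it shallower than `min_depth` it merges
   into the nearest deeper basin.
3. **Negligible population.**  Basins holding under `min_population`
   (default 1%) of the frames fold into their nearest deeper neighbor:
   Boltzmann inversion of one-count bins manufactures minima no depth
   criterion can reject, and conformers weighted below 1% would not be
   carried into quantum-chemistry calculations anyway.

Basin probability is the member-frame fraction of *all* frames, so the
probabilities sum to the retained fraction (≤ 1); `renormalize()`
rescales them to sum to one before spectrum weighting.  The
representative structure is the frame whose projection is nearest the
basin's mode bin (not the centroid — robust for curved basins).  Final
weights are the product measure w₍ⱼᵢ₎ = pᵢ · p₍ⱼᵢ₎ over solute and
cluster basins.

The convergence check reruns the full ED + landscape + basin pipeline on
three contiguous blocks and compares matched basin weights (matching by
mode-bin proximity in projection space).  If the blocks disagree on the
basin count the report flags the mismatch and refuses to pair anything.

## Constraint specifications for quantum chemistry

For a representative frame the emitted frozen coordinates are: the
user-declared solute torsions; each solvent molecule's center of mass in
spherical coordinates (physics convention — θ polar from +z, φ from +x)
in the mass-weighted solute principal frame, which makes the values
frame-independent when the solute is frozen; three rigid-body orientation
torsions per solvent molecule built from its first two atoms and the two
solute atoms nearest its center of mass (a deterministic anchor rule);
and the solvent template's internal torsions (none for water, the two
methyl rotations for DMSO).  The output is neutral commented text; no QM
engine input format is generated.

## Spectra

The Gaussian bandwidth Δ is the half-width at 1/e of peak height:
I(ν₀ ± Δ) = I(ν₀)/e by construction.  Default Δ = 7.0 cm⁻¹ and grid
spacing 1 cm⁻¹.  Broadened intensity is proportional to the rotational
strength alone; since every comparison is made on normalized intensities
a constant prefactor cancels, and a ν-weighted variant exists behind a
flag (off by default).  No harmonic frequency scaling is applied unless
requested.  Assembly requires an exactly shared grid (no silent
resampling) and renormalizes the weights to sum to one by default.
Normalization scales to max |I| = 100.  The agreement RMSD resamples
both spectra linearly onto a uniform grid over an explicit window,
normalizes each on that window, and takes the root-mean-square
difference; it is symmetric, zero on identical shapes, invariant to
uniform scaling of either input, and window-dependent by design.

## The synthetic generator

The generator emulates the configurational structure the pipeline must
resolve: a rigid solute with interaction sites, a bound solvent
population hopping among a catalog of site-bound arrangements with
prescribed weights, and bulk solvent scattered uniformly in an outer
shell.  Frames are i.i.d. draws — there are no dynamics, no
hydrogen-bond network, no force field, and no pressure/temperature
coupling.  Passing tests therefore demonstrate that the selection,
covariance and weighting machinery recovers known configurational ground
truth; they say nothing about force-field quality or sampling length on
real trajectories, which the convergence check addresses only partially.

The stock fixture is an L-alanine-like zwitterion (13 atoms, idealized
geometry) in water: two waters on each carboxylate oxygen and three on
the ammonium nitrogen, placed on cones (half-angle 35°) at staggered
distances 0.7–0.9 Å apart with hydrogens pointing away from the site.
The staggering and orientation make the distance ranking of the bound
waters deterministic under the positional noise (σ = 0.15 Å), so slot
identities do not permute between frames — permutation would fragment
the projection clusters.  The four arrangements rotate every bound water
azimuthally about its own site axis by a common angle (steps of 30°);
because all waters share one angle, each atom's position is affine in
(cos, sin) of it, so the four arrangement means span exactly a 2-D plane
of configuration space and two essential eigenvectors carry the
transition.  Default weights are 0.15/0.25/0.40/0.20 and 8 bulk waters
(15 solvent molecules in all); the bulk shell (9–13 Å) starts well
outside the outermost bound anchor so bulk never outranks bound solvent
at a center.

## Problem sizes and determinism

The test suite runs the recovery experiment at 50 000 frames, the
three-way convergence check at 30 000 frames, and oracle equivalences at
12–60 frames; the full suite completes in well under a minute on one
CPU.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); reruns with the same configuration are
bit-identical on one platform.

## Known limitations

- Heterogeneous or multi-species solvents are rejected.
- The greedy conflict resolution is order-dependent in pathological
  near-tie geometries; it is deterministic but not globally optimal.
- Basin boundaries depend on the binning; the defaults suit 10⁴–10⁵
  frame trajectories and must be reduced for short blocks.
- Binary trajectory formats (XTC/DCD) are not read; convert externally
  to multi-frame PDB/GRO or extended XYZ.
- The spectrum-agreement RMSD convention (normalization to 100, 1 cm⁻¹
  resampling, window as given) is declared here and config-exposed;
  other conventions in the literature differ by scale.
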