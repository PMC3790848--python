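# Methods

This note documents the models and procedures corestab implements, the
parameter choices behind them, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Structure model and input handling

A structure is a flat, ordered list of atom records (author residue
numbering, coordinates in Å) grouped into residue views on demand; an
ensemble is one such topology plus a stack of coordinate frames.  PDB reading
and writing go through gemmi; waters and common monoatomic ions are dropped
on input, except zinc, which p53-family domains bind structurally — zinc is
kept and listed in `Structure.zinc_atoms`, and all protein residues
(including the zinc-coordinating ones) enter the wrapping and SASA sums.
Alternate locations default to the highest-occupancy conformer (ties resolve
toward altloc A) so every downstream count sees a single deterministic
conformer; `altloc_policy="all"` keeps everything.  Hydrogens present in a
file are retained but ignored by the heavy-atom analyses; the amide hydrogen
needed by the H-bond energy is always rebuilt (below), never taken from the
file.  Covalent bonds, where needed, are inferred from heavy-atom distances
below 1.9 Å — an upper bound chosen to cover C–S bonds without a chemical
dictionary.

For multi-copy crystals the analyses default to chain A (overridable
everywhere); the chain actually used is echoed in the profile metadata.

## Backbone hydrogen bonds and wrapping

Bond calling follows the DSSP convention.  The donor amide hydrogen is placed
1.00 Å from N along the unit vector opposite the preceding residue's C→O
bond; prolines and chain-initial residues cannot donate.  The bond energy is
the Kabsch–Sander electrostatic model,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, floored at
−9.9 kcal/mol against near-contact singularities; a pair is a bond when
E ≤ −0.5 kcal/mol.  Candidate pairs are limited to donor/acceptor residues
whose Cα atoms lie within 9 Å (a standard prescreen that cannot exclude a
real bond at these energies), with an intra-chain sequence separation of at
least 2 positions, and at most the two lowest-energy acceptors are kept per
donor, as in DSSP.

Wrapping of a bond counts the *distinct* nonpolar carbons inside the union of
two 6.5 Å spheres centred on the donor and acceptor Cα.  A carbon is nonpolar
("carbonaceous CH group") when no covalently bonded heavy neighbour is N, O
or S; the donor's and acceptor's own carbons participate, because the domain
is defined purely geometrically.  Counting the union rather than the two
spheres separately avoids double-counting shared carbons, which would roughly
double the per-structure mean ρ.  Vulnerable bonds (dehydrons) are those with
wrapping ≤ 16, inclusive; the threshold is a parameter, and
`calibrate_threshold` re-derives it from a background structure set as the
largest *observed* wrapping t with P(wrapping ≤ t) ≤ tail_fraction.  The
observed-value convention matters: any integer between two observed counts
leaves the empirical tail unchanged, so quantising to observed values makes
the rule reproducible; with tail_fraction = 0 the threshold falls below the
minimum observed count and nothing is vulnerable.  The tail fraction itself
is exposed rather than fixed, since the published protocol states the
resulting threshold (16) but not the tail mass used to derive it.

## Solvent accessibility and interfaces

SASA is Shrake–Rupley: each heavy atom carries n quasi-uniform points
(generalised golden-section spiral — deterministic, so outputs are
bit-reproducible without a seed) on its solvent-expanded sphere of radius
r_vdw + 1.4 Å, and its area is the unoccluded fraction times the sphere area.
Radii are Chothia-type: C 1.70, N 1.55, O 1.52, S 1.80 Å (P 1.80, Se 1.90,
Zn 1.39 for completeness).  The default n = 960 keeps per-residue areas
converged to better than 1% (doubling the point count is one of the test
invariants); tests against a 10⁵-point Monte-Carlo oracle hold per-atom to 2%
with a 0.5 Å² absolute floor, because the relative error of a nearly buried
atom (a few Å² of residual area) is dominated by both estimators' sampling
granularity and is not a meaningful convergence measure.

Residue exposure uses the whole-residue convention (backbone + side chain).
Interface detection follows the component-deletion operation: each residue's
SASA in the full complex is compared with its SASA in its isolated component
at identical coordinates, and a relative reduction ≥ 10% (inclusive) makes it
an interface residue; residues with zero isolated SASA never qualify.
Side-chain-only exposure is deliberately not the default — the published
whole-residue magnitudes (e.g. ~86 Å² for an exposed tryptophan) match the
whole-residue convention.  Interface propensity pools counts per residue type
over a dataset of complexes, p = n_interface / n_total; an exposure filter,
when given, applies to numerator and denominator alike, and empty
denominators are reported as undefined rather than zero.

## Secondary structure

One pattern-based assigner serves all inputs (the published protocol used
STRIDE for trajectory frames and DSSP-derived bonds elsewhere; STRIDE's
fitted energy/dihedral parameters are not public, so a single in-repo
algorithm was preferred, at the cost of up to ±3 percentage points against
printed STRIDE contents).  From the Kabsch–Sander bond set: an n-turn at i is
a bond C=O(i)←N-H(i+n) for n = 3, 4, 5; two consecutive 4-turns assign an
α-helix (H) over residues i..i+3; parallel/antiparallel bridge patterns give
bridges, consecutive bridges form ladders (E), isolated ones stay B;
remaining turn spans are T, the rest coil.  Priority is H, then E/B, then
G/I, then T.  Simplified classes: helix = {H,G,I}, sheet = {E,B} (isolated
bridges count as sheet, the usual convention for content percentages).
Segments are maximal simplified runs, labelled S1…/H1… in sequence order;
strands shorter than 2 or helices shorter than 4 residues fall to "other".
Inter-strand H-bond counts take both bond directions between two disjoint
segments.

## Ensemble observables

Superposition is the Kabsch SVD fit with proper-rotation correction; fewer
than three points or collinear references are rejected.  RMSD series fit each
frame to the reference over the selection and report the RMSD over that same
selection.  RMSF is measured about the iterated mean structure (two passes of
fit-to-mean — standard practice, and the reference the figures of interest
leave unspecified); a separate fit selection may be supplied, and fitting on
all atoms while measuring at Cα is recommended, since a small fit set lets
superposition jitter leak into the apparent fluctuation of quiet residues.
H-bond time series come in two modes: backbone (Kabsch–Sander, consistent
with the wrapping stage) and all-donor geometric (donor–acceptor < 3.5 Å,
antecedent–donor–acceptor angle > 120°), because trajectory H-bond counts are
conventionally geometric.  Salt bridges pair ASP/GLU carboxylate oxygens with
LYS NZ, ARG NE/NH, or HIS ND1/NE2 within 4.0 Å (histidine included because
Glu–His contacts are part of the stability story in these domains;
protonation is not modelled); ensemble occupancy is the fraction of frames
within the cutoff.  PCA diagonalises the 3N positional covariance of the
superposed selection (Cα by default, no mass weighting) via SVD of the
centred frame matrix; a mode's contribution is 100·λ_k/Σλ, and the eigenvalue
sum equals the total superposed variance to machine precision (a test
invariant).

## Synthetic data: what it emulates, and what it does not

The generator provides the statistical and geometric structure the analyses
assume, with exact ground truth:

* ideal α-helices and extended chains from canonical internal coordinates
  (N–CA 1.458, CA–C 1.525, C–N 1.329 Å, ω = 180°; φ/ψ = −57°/−47° and
  −139°/135°), alanine-like residues (N, CA, CB, C, O) by default — an ideal
  n-residue helix carries exactly n−4 i+4→i bonds;
* β-hairpins with a designed antiparallel ladder: strand B is placed rigidly
  by minimising a distance-geometry objective (N···O = 2.9 Å, H···O = 1.9 Å
  per designed bond, plus a clash penalty) from deterministic antiparallel
  starts, and a short turn is attached whose last carbonyl is engineered to
  give the first B-strand donor its ideal amide-H direction;
* hydrophobic decorations: bare pseudo-carbons at caller-chosen offsets
  (clashes < 1.5 Å are refused), so wrapping counts are fully controllable
  without rotamer chemistry;
* dimers with a designed contact patch: a two-sided glycine "sandwich" buries
  the patch from both faces of the extended chain — one-sided partners cannot
  bury residues whose side chains point away — and a bounded deterministic
  search over the approach distance (then segment length and lateral shift)
  finds a placement where exactly the patch residues of chain A lose ≥ 10%
  SASA;
* Gaussian ensembles: per-residue isotropic noise of amplitude a (expected
  RMSF = a√3) plus collective modes with chosen variances; mode fields are
  projected off the 6-dimensional rigid-body subspace of the base structure,
  because superposition removes that subspace and an unprojected mode would
  lose variance in every fitted observable.

Every generator verifies its own ground truth before returning (bond sets by
re-extraction, wrapping by an independent O(n²) double loop, interfaces by
the surface module, ensemble RMSF empirically at ≥ 200 frames), so generator
bugs fail loudly at generation time.

What the fixtures do *not* emulate: real side-chain chemistry and rotamers,
sequence-dependent wrapping heterogeneity, solvent structure, anharmonic or
time-correlated dynamics, and the curated background sets (transient/obligate
complexes; non-redundant interfaces) behind the published threshold of 16 and
the tryptophan propensities (p = 0.175 overall, 0.565 above 80 Å²).  Passing
the synthetic suite therefore demonstrates algorithmic correctness — the
statistics recover designed truth under the stated conditions — not that any
particular biological conclusion re-derives; the crystal-structure
reproductions (mean wrapping ρ, Trp146 exposure, contents, S1–S4 counts) run
only when the PDB entries are supplied under `data/pdb/`.

## Study conditions used by the tests and the acceptance script

Fixture sizes were chosen so each estimator is measured where sampling theory
says the stated tolerance is attainable: helices of 4–30 residues for the
closed form; 100 randomized decorated helices (6–12 residues, 1–6
decorations) for the wrapping oracle; 20 seeded dimers (8–14 residues,
patches of 2–4) for interface recovery; a 60-residue extended chain with a
0.5/1.0/2.0 Å three-level profile at 500 frames for RMSF (per-residue
sampling error ≈ 1/√(2F) ≈ 3.2%, so the 5% check uses the all-atom fit
selection); 1000 frames for the 3:1 two-mode PCA ratio (±3 points).  The
10%/90% two-level background {10×20, 90×30} checks the threshold-calibration
tail rule exactly.

## Known limitations

* The SASA algorithm is numerical (Shrake–Rupley), not the analytical
  POPS-family model used in the original protocol; per-residue areas agree
  with converged numerical values, but parameter-fitted analytical areas can
  differ by several percent — reproduction tolerances on published SASA
  values are ±10% accordingly.
* The secondary-structure assigner is DSSP-pattern-based, not STRIDE;
  printed STRIDE contents are matched to ±3 percentage points, not exactly.
* Segment labels (S1…, H1…) are assigned by sequence order, so mapping to a
  publication's named elements depends on the same strands being found; the
  inter-strand count checks are conditional on that identification.
* Salt-bridge detection is a distance criterion on charged heavy atoms;
  protonation states and bridging waters are out of scope.
* Proline and chain-initial residues never donate; missing backbone atoms
  drop a residue from bond extraction with a logged warning rather than an
  error, so sparsely resolved inputs should be checked against the log.
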