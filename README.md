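# corestab

Structural-stability profiling of protein domains: backbone hydrogen-bond
wrapping (dehydron analysis), solvent-accessible surface areas and
protein–protein interface statistics, H-bond-pattern secondary structure, and
conformational-ensemble observables (RMSD, RMSF, salt bridges, Cα PCA).

The package was built to compare the intrinsic stability of evolutionarily
related DNA-binding domains — the p53/p63/p73 family being the motivating
case — from their coordinates alone: which homologue wraps its backbone
hydrogen bonds best, which solvent-exposes an aromatic that its stabler
relatives replace, how strand pairings and salt-bridge networks differ, and
how those differences show up in conformational ensembles.  All stages run
equally on crystal structures, homology models, or multi-model coordinate
files standing in for MD trajectory frames, and a synthetic-structure
generator provides fixtures with exact ground truth so every stage is
testable offline.

## The quantities it computes

**Backbone H-bond wrapping.**  Backbone N–H···O=C bonds are called with the
Kabsch–Sander electrostatic model used by DSSP,

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol,

with a bond whenever E ≤ −0.5 kcal/mol (amide hydrogens are rebuilt 1.00 Å
from N, anti to the preceding C→O).  The *wrapping* of a bond is the number
of nonpolar ("CH") carbons inside its desolvation domain — the union of two
6.5 Å spheres centred on the two Cα atoms.  A structure is summarised by the
mean wrapping ρ and by its count of *vulnerable bonds* (dehydrons): bonds in
the low tail of a background wrapping distribution, by default wrapping ≤ 16.
`calibrate_threshold` re-derives that threshold from any background set.

**Surfaces and interfaces.**  SASA by the Shrake–Rupley method on a
deterministic spiral point set (Chothia-type radii, 1.4 Å probe).  A residue
of a two-chain complex is an interface residue when it loses ≥ 10% of the
SASA it has in its isolated component; interface propensity of an amino-acid
type is the fraction of its occurrences that are interface residues, with an
optional minimum-exposure filter.

**Secondary structure.**  Per-residue H/G/I/E/B/T/C classes from the
Kabsch–Sander bond pattern (n-turns and bridge ladders), content percentages
(helix = H/G/I, sheet = E/B), labelled segments (S1…, H1…), and inter-strand
H-bond counts between any two segments.

**Ensembles.**  Kabsch superposition, RMSD series, per-residue RMSF about the
iterated mean structure, per-frame intramolecular H-bond counts, salt-bridge
detection with occupancies (charged side-chain atoms within 4 Å), and PCA of
the positional covariance with per-mode contribution percentages.

## Worked example

```python
from corestab import assign_ss, segments, interstrand_hbonds, wrapping_profile
from corestab.synthetic_data import make_hairpin

hairpin, truth = make_hairpin(6)          # two 6-residue antiparallel strands
assignment = assign_ss(hairpin)
print("".join(assignment.per_residue[r.key] for r in assignment.residues))
strands = [s for s in segments(assignment) if s.ss_class == "sheet"]
print(interstrand_hbonds(hairpin, strands[0], strands[1], bonds=assignment.bonds))
print(f"{wrapping_profile(hairpin).rho:.2f}")
```

prints

```
CEEEEETTEEEEEC
6
4.62
```

The assigner finds the two strands (`E`) and the turn (`T`); the strands are
zipped by 6 backbone H-bonds — exactly the designed ladder, and the same
count used to compare S1–S4 pairing between homologous domains (a worm-like
elongated S1 gives 6 where the human domain gives 4); the mean wrapping of
4.62 carbons per bond says a bare poly-alanine hairpin is very poorly wrapped
(every bond a dehydron at the ≤ 16 threshold), as expected with no
hydrophobic core around it.

The `examples/` directory has one narrative script per capability
(wrapping, interfaces/propensity, secondary structure, ensembles,
salt bridges + the one-call profile).  A thin CLI mirrors the library:
`corestab profile <pdb> --chain A --out report/`,
`corestab wrap|sasa|interface|ss|strandpair|flex|saltbridges|pca|synth ...`.

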