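# Methods

## Problem and model

Two included topologies describe the same molecule under different force
fields when their element-labeled molecular graphs are isomorphic. The
graph model deliberately discards everything force fields disagree on
(atom types, names, charges, bond orders, aromaticity, stereochemistry)
and keeps only what they must share: the atoms' chemical elements and the
covalent connectivity. Classical force fields treat every bond as a
harmonic spring, so each bond contributes exactly one undirected edge.
The mapping produced by the isomorphism is a permutation of 1-based atom
indices; conversion is purely a per-molecule permutation of the
coordinate file plus renaming from the target topology.

Assumptions inherited from this model:

- **Same protonation and same tautomer on both sides.** A proton added
  or removed changes the graph; the matcher then correctly reports
  non-isomorphism. There is no search timeout by default; the optional
  wall limit (`--wall_limit`) aborts with guidance that a search running
  for many minutes usually indicates such a mismatch rather than a hard
  instance.
- **No water-model changes.** Converting a 3-site water to a 4-site
  model would require creating a virtual site with new coordinates,
  which is out of scope; both topologies must have the same atom count
  per molecule.
- **Automorphic atoms are interchangeable.** Hydrogens on the same
  carbon (and symmetric ring positions) can be swapped by a graph
  automorphism; any of the resulting mappings gives identical energies.
  Diastereotopic hydrogens are parametrized identically by standard
  force fields, so this does not affect simulation validity — only
  name-based analyses, which is what the consistent-naming constraint
  table is for.

## Element inference

The element of each atom is the nearest standard atomic weight
(conventional values for elements 1–86) to the mass column of the
`[ atoms ]` block, accepted only when the difference is at most the
tolerance of 0.3 amu. The tolerance is deliberately tight: deuterium
(2.014), heavy-hydrogen repartitioning schemes and massless/light
virtual sites all fall outside every window and abort the run instead of
mislabeling nodes. An exact tie between two elements also aborts (no
standard atomic weights are closer than twice the tolerance, so this
only triggers for pathological custom tables). Masses are read from the
per-atom column only; `[ atomtypes ]` lookups are not performed, so each
molecule file must be self-contained. Isotopically labeled topologies
fail by design.

## Matching algorithm

The matcher is a VF2-style backtracking search with the following fixed,
fully deterministic order, chosen for reproducibility (identical inputs
always return the identical mapping):

- seed node: rarest element in the molecule, then highest degree, then
  lowest index;
- next node to extend: the unmapped node with the most already-mapped
  neighbors, then highest degree, then lowest index (the frontier is
  never empty for a connected graph);
- target candidates: ascending index.

Feasibility of a candidate pair: equal element (semantic); the mapped
neighbors of the source node must map exactly onto the mapped neighbors
of the candidate (this enforces adjacency *and* non-adjacency within the
mapped set); and the unmapped one-hop neighborhoods must agree element
by element (a cheap look-ahead that prunes almost all dead branches for
molecular graphs). Cheap global prechecks (atom count, element multiset,
degree histogram) reject obvious non-matches before any search.

Search time depends on molecular symmetry, not just size, and is
direction-sensitive: matching A→B and B→A can differ by orders of
magnitude because the node orderings differ. This asymmetry is inherent
to first-found backtracking; when one direction is slow, running the
other direction and inverting the stored mapping (swap the two columns,
resort by the new first column) is equivalent and is exactly what
`invert_mapping` does.

Name constraints are resolved before the search: each CSV pair pins one
source atom to one target atom, after checking that both names exist,
are unique in their topology, and label atoms of the same element
(a cross-element pin is a hard error raised before searching).
Unconstrained atoms are mapped by element and connectivity alone. A
missing CSV header cannot be detected with certainty; the implemented
heuristic rejects the file when its first row names real atoms in both
topologies, which catches the common mistake without false-positive risk
from conventional headers.

The brute-force oracle enumerates all element-compatible index
assignments (capped at 10 atoms, beyond which enumeration is
combinatorially useless) and is kept entirely independent of the search
path; the test suite also cross-checks existence against networkx's
matcher on random graphs.

## Conversion and numbering

Segmentation of the system file is purely arithmetic — molecule counts
times atoms per molecule, in the user-stated order. Residue labels in
the source file are never trusted (naming conventions are exactly what
differs between force fields); an inconsistent residue-number pattern
only logs a warning. Output atom numbers run 1..N and residue numbers
increment at every molecule start and at every residue boundary *of the
target topology*, which also handles molecules that one force field
splits into more residues than the other. Display numbers wrap modulo
100000 to fit the fixed 5-column fields, as GROMACS itself prints them.
Velocities, when present, travel with their atom through every
permutation; discarding them would silently change restart behavior.
Position-restraint records are renumbered through the same mapping with
force constants untouched.

Back-conversion composes the inverse mappings with the converted file
and must restore the original atom order and coordinates exactly; this
order-identity plus coordinate-equality check is the package's
validation criterion (a single-point-energy comparison would need a full
MD engine and adds nothing for a pure permutation).

## Synthetic fixtures

The generator emulates what system-preparation pipelines produce:
single-molecule topologies, a "second force field" variant (atoms
randomly permuted, bonds re-indexed, names deterministically mangled,
residues re-chunked) with the ground-truth permutation recorded, and
packed coordinate files with seeded uniform coordinates at roughly
liquid-water atom density (100 atoms/nm³), quantized to the .gro printed
precision (3 decimals nm, 4 decimals nm/ps) so file round trips are
exact. All randomness is seeded; the same seed reproduces the same
fixture bit for bit.

Lipid- and protein-chain stand-ins are constructed trees at exact atom
counts: c carbons in a random tree, (n−2) mod 3 ether oxygens spliced
into C–C edges, hydrogens filling every carbon to valence 4
(3c + o + 2 = n). They reproduce the size and connectivity class of real
lipids — element-labeled connected sparse graphs — not their chemistry.
Passing tests therefore demonstrate mapping validity, conservation,
numbering and count arithmetic on realistic graph shapes and sizes; they
do not exercise real CHARMM/AMBER atom-type conventions, disulfide
topology or exotic ITP dialects (`#include` trees are rejected
explicitly). The membrane benchmark composition (11 species, 675,234
molecules, 2,270,122 atoms, of which 668,899 three-site waters =
2,006,697 atoms) is generated at full scale and pushed through the real
CLI; it completes in about a minute on one CPU, which is why no
scaled-down variant is needed.

The permutation-recovery check needs a molecule whose automorphism group
is trivial; any hydrogen-decorated organic has H-swap automorphisms, so
the fixture set includes a small heteroatom tree (S–C–C(–O)–C–N, heavy
atoms only) whose triviality the brute-force oracle verifies inside the
test rather than assumes.

## Numerical and design choices

- Coordinates are carried as parsed floats and reprinted with the
  standard fixed formats; the converter never does arithmetic on them,
  so conversion is lossless by construction.
- ITP dialect: one molecule per file; preprocessor directives raise an
  unsupported-dialect error instead of being half-interpreted.
- The settles oxygen is the atom at the block's first index and its two
  partners are simply the remaining atoms of the 3-atom molecule, so a
  permuted rigid water still builds the correct star graph; no H–H edge
  is added, keeping SETTLE waters isomorphic to two-bond water
  topologies from bonded force fields.
- Mapping files are CSV with a `source,target` header, 1-based indices
  sorted by source — human-editable and trivially invertible.
- The mapping database is a plain directory with per-molecule atomic
  file writes; concurrent `ffmap` runs on different molecules are safe,
  concurrent writers to the same molecule are not guarded.

## Known limitations

- No subgraph or partial matching: the coordinate file must be fully
  covered by the stated composition, and trailing unexplained atoms are
  an error.
- No canonical preference among automorphic mappings absent a naming
  CSV; two runs of different tool versions may legitimately differ by an
  automorphism.
- Only the Gromos87 `.gro` coordinate format and single-molecule `.itp`
  topologies are supported; no PDB/PSF/CRD, no full `.top` parsing.
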