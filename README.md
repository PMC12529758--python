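# ffremap

Convert GROMACS systems between all-atom force fields by molecular-graph
matching.

GROMACS requires the atom order of the coordinate file to match the
topology exactly, but every force-field family (CHARMM, AMBER, ...) uses
its own atom names, residue names and atom ordering for the same
molecule. A system prepared and equilibrated under one force field
therefore cannot simply be handed to another force field's topology.
ffremap is for force-field developers and practitioners who want to run
the *same starting coordinates* under two parametrizations: it resolves
the ordering and naming mismatch automatically, without templates,
without modifying any parameters, and without touching a single
coordinate.

## How it works

Each molecule type's included topology (`.itp`) is turned into a
**molecular graph**: one node per atom, labeled with the chemical element
inferred from the mass column (closest standard atomic weight, rejected
if no element lies within 0.3 amu — virtual sites and repartitioned
hydrogens fail loudly rather than silently), and one edge per entry of
the `[ bonds ]` block. Rigid SETTLE waters have no bonds block; their
`[ settles ]` block contributes the two O–H edges instead.

The two graphs are then matched by a deterministic VF2-style backtracking
search: a partial node mapping is extended one feasible pair at a time,
where feasibility means equal element labels, consistent edges to the
already-mapped set in both directions, and matching element counts in
the unmapped one-hop neighborhoods. If the molecules are the same, a
mapping is guaranteed to be found; the first one found under the fixed
search order is returned (molecules with automorphisms — e.g. the two
hydrogens on one CH2 — admit several equally valid mappings, all
physically identical). If the molecules differ (wrong file, protonation
mismatch), the search reports that the graphs are not isomorphic.

The resulting mapping `m` (a bijection of 1-based atom indices,
`source → target`) is stored in a reusable database directory, one
`<name>.map.csv` per molecule type. The converter then walks the
coordinate file molecule by molecule (the user supplies names and counts
in file order), places the source atom at position *i* of each molecule
at target position *m(i)*, takes atom and residue names from the target
topology, renumbers atoms 1..N and residues sequentially, and copies
coordinates, velocities and box unchanged. Position-restraint files can
be renumbered with the same mapping. Back-conversion (`--validate`)
applies the inverse mapping — the stored file with columns swapped and
resorted — and must restore the original order and coordinates exactly.

## Worked example

Map a phenylacetic-acid ligand (18 atoms) between two force-field
conventions and reorder its coordinate file. The fixture generator
stands in for real force-field files; any pair of single-molecule ITPs
works the same way.

```sh
$ ffremap ffmap -name BZAA -itp1 BZAA_charmm.itp -itp2 mappings/BZAA.itp \
      -mapping_dir mappings --validate
BZAA: mapping of 18 atoms written to mappings/BZAA.map.csv
BZAA: validation passed (isomorphism and inverse verified)

$ head -4 mappings/BZAA.map.csv
source,target
1,11
2,1
3,10
```

Row `1,11` says: atom 1 of the current force field (the ring carbon
bonded to the CH2 group) is atom 11 in the new force field's ordering,
and its coordinates will be emitted at position 11 of each converted
molecule.

```sh
$ ffremap groconv -coordfile ligand.gro -name BZAA -nmol 1 \
      -output ligand_amber.gro -mapping_dir mappings --validate --no-prompt
wrote 18 reordered atoms to ligand_amber.gro
validation passed: round-trip atom order and coordinates identical
```

The output file carries the new force field's atom and residue names
with atoms renumbered from 1, and the round-trip check confirms that
applying the inverse mapping reproduces the input ordering bit for bit.
For multi-species systems list every molecule name and count in file
order (`-name SOL K BZAA -nmol 668899 2128 1`); the target force field's
`<name>.itp` files are picked up from the mapping directory
automatically, so a mapping database built once serves every subsequent
conversion.

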