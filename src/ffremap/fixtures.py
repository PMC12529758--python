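"""Synthetic molecules, force-field variants and packed systems.

Everything the converter consumes can be generated here with known ground
truth: chemically consistent molecule topologies (rigid water with a
settles block, monatomic ions, alkanes, benzene, phenylacetic acid, and
tree-shaped lipid/protein stand-ins at any requested atom count), a
"second force field" variant of any topology (atoms permuted, names
mangled, residues re-chunked) with the permutation recorded, and packed
coordinate files with seeded random coordinates.

The stand-in molecules reproduce the size and connectivity class of real
lipids and protein chains — element-labeled connected graphs at exact atom
counts — not their chemistry; mapping validity, conservation and count
arithmetic depend only on graph structure and counts.

All randomness is seeded; the same seed always yields the same fixture.
"""

from __future__ import annotations

import random
from typing import Optional

import numpy as np

from .gro import AtomRecord, CoordinateFile
from .converter import SystemComposition
from .topology import (
    Bond,
    MoleculeTopology,
    PosResRecord,
    SettlesRecord,
    TopAtom,
    infer_element,
)

__all__ = [
    "make_molecule",
    "make_variant",
    "make_system",
    "MEMBRANE_BENCHMARK",
]

_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.9994, "P": 30.974,
    "S": 32.06, "K": 39.098, "Cl": 35.45,
}

# Large solvated lipid-membrane benchmark composition: 11 species,
# 675,234 molecules, 2,270,122 atoms in total.  Each entry is
# (molecule name, molecule count, recipe).
MEMBRANE_BENCHMARK = (
    ("CHL", 705, "lipid:74"),
    ("DPPC", 94, "lipid:130"),
    ("PSM", 470, "lipid:127"),
    ("DPPE", 282, "lipid:121"),
    ("POPE", 423, "lipid:125"),
    ("POPC", 141, "lipid:134"),
    ("POPS", 141, "lipid:127"),
    ("DPPS", 94, "lipid:123"),
    ("K", 2128, "ion:K"),
    ("CL", 1857, "ion:Cl"),
    ("SOL", 668899, "water"),
)


def _atom(i, elem, name, res_index=1, res_name="MOL", type_name=None, charge=0.0):
    return TopAtom(
        index=i,
        type_name=type_name or elem.lower() + "t",
        res_index=res_index,
        res_name=res_name,
        atom_name=name,
        charge=charge,
        mass=_MASS[elem],
    )


def _water(name: str) -> MoleculeTopology:
    atoms = [
        _atom(1, "O", "OW", res_name="SOL", type_name="OWt", charge=-0.834),
        _atom(2, "H", "HW1", res_name="SOL", type_name="HWt", charge=0.417),
        _atom(3, "H", "HW2", res_name="SOL", type_name="HWt", charge=0.417),
    ]
    return MoleculeTopology(
        mol_name=name, atoms=atoms,
        settles=SettlesRecord(ow=1, d_oh=0.09572, d_hh=0.15139),
    )


def _ion(name: str, elem: str) -> MoleculeTopology:
    charge = -1.0 if elem == "Cl" else 1.0
    res = elem.upper()
    return MoleculeTopology(
        mol_name=name,
        atoms=[_atom(1, elem, res, res_name=res, type_name=elem, charge=charge)],
    )


def _alkane(name: str, k: int) -> MoleculeTopology:
    """Linear alkane C_k H_{2k+2}."""
    if k < 1:
        raise ValueError("alkane needs at least one carbon")
    atoms, bonds = [], []
    for c in range(1, k + 1):
        atoms.append(_atom(c, "C", f"C{c}"))
        if c > 1:
            bonds.append(Bond(c - 1, c))
    idx = k
    for c in range(1, k + 1):
        n_h = 4 - sum(1 for b in bonds if c in (b.i, b.j))
        for _ in range(n_h):
            idx += 1
            atoms.append(_atom(idx, "H", f"H{idx - k}"))
            bonds.append(Bond(c, idx))
    return MoleculeTopology(mol_name=name, atoms=atoms, bonds=bonds)


def _benzene(name: str) -> MoleculeTopology:
    atoms = [_atom(i, "C", f"C{i}", res_name="BNZ") for i in range(1, 7)]
    atoms += [_atom(i + 6, "H", f"H{i}", res_name="BNZ") for i in range(1, 7)]
    bonds = [Bond(i, i % 6 + 1) for i in range(1, 7)]
    bonds += [Bond(i, i + 6) for i in range(1, 7)]
    return MoleculeTopology(mol_name=name, atoms=atoms, bonds=bonds)


def _phenylacetic_acid(name: str) -> MoleculeTopology:
    """C6H5-CH2-COOH: 18 atoms, 18 bonds (one ring)."""
    res = "BZAA"
    atoms = [_atom(i, "C", f"C{i}", res_name=res) for i in range(1, 7)]   # ring
    atoms += [
        _atom(7, "C", "C7", res_name=res),    # CH2
        _atom(8, "C", "C8", res_name=res),    # carboxyl C
        _atom(9, "O", "O1", res_name=res),    # C=O
        _atom(10, "O", "O2", res_name=res),   # C-O(H)
    ]
    atoms += [_atom(10 + i, "H", f"H{i}", res_name=res) for i in range(1, 9)]
    bonds = [Bond(i, i % 6 + 1) for i in range(1, 7)]          # ring
    bonds += [Bond(i + 1, 10 + i) for i in range(1, 6)]        # ring H on C2..C6
    bonds += [
        Bond(1, 7),            # ring-CH2
        Bond(7, 16), Bond(7, 17),   # CH2 hydrogens
        Bond(7, 8),            # CH2-C(O)
        Bond(8, 9),            # C=O
        Bond(8, 10),           # C-O
        Bond(10, 18),          # O-H
    ]
    return MoleculeTopology(mol_name=name, atoms=atoms, bonds=bonds)


def _asym(name: str) -> MoleculeTopology:
    """A 6-atom heteroatom tree (S-C-C(-O)-C-N) with a trivial automorphism
    group: every node is distinguished by element or neighborhood."""
    res = "ASY"
    atoms = [
        _atom(1, "S", "S1", res_name=res),
        _atom(2, "C", "C1", res_name=res),
        _atom(3, "C", "C2", res_name=res),
        _atom(4, "C", "C3", res_name=res),
        _atom(5, "N", "N1", res_name=res),
        _atom(6, "O", "O1", res_name=res),
    ]
    bonds = [Bond(1, 2), Bond(2, 3), Bond(3, 4), Bond(4, 5), Bond(3, 6)]
    return MoleculeTopology(mol_name=name, atoms=atoms, bonds=bonds)


def _heavy_tree(name: str, n_atoms: int, seed: int, res_chunks: int = 1,
                res_name: str = "LIP") -> MoleculeTopology:
    """Connected tree at an exact atom count: c carbons in a random tree,
    o = (n-2) mod 3 ether oxygens spliced into C-C edges, and hydrogens
    filling every carbon to valence 4 (total = 3c + o + 2 = n)."""
    if n_atoms < 5:
        raise ValueError("tree stand-ins need at least 5 atoms")
    o = (n_atoms - 2) % 3
    c = (n_atoms - 2 - o) // 3
    rng = random.Random(seed)

    # random carbon tree, max heavy degree 4
    parent: dict[int, int] = {}
    heavy_deg = [0] * (c + 1)
    for v in range(2, c + 1):
        choices = [u for u in range(1, v) if heavy_deg[u] < 4]
        u = rng.choice(choices)
        parent[v] = u
        heavy_deg[u] += 1
        heavy_deg[v] += 1
    edges = [(parent[v], v) for v in range(2, c + 1)]

    # splice o oxygens into distinct C-C edges
    heavy_elems = ["C"] * c
    next_idx = c
    if o:
        if not edges:
            raise ValueError("cannot splice oxygens into a single-carbon tree")
        chosen = rng.sample(range(len(edges)), min(o, len(edges)))
        for k in sorted(chosen, reverse=True):
            u, v = edges.pop(k)
            next_idx += 1
            heavy_elems.append("O")
            edges += [(u, next_idx), (next_idx, v)]

    # hydrogens on carbons up to valence 4
    deg = [0] * (next_idx + 1)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    h_edges = []
    for u in range(1, c + 1):
        for _ in range(4 - deg[u]):
            next_idx += 1
            heavy_elems.append("H")
            h_edges.append((u, next_idx))
    edges += h_edges
    assert next_idx == n_atoms, (next_idx, n_atoms)

    n = n_atoms
    bounds = [round(k * n / res_chunks) for k in range(res_chunks + 1)]
    res_of = [0] * (n + 1)
    for r in range(res_chunks):
        for i in range(bounds[r] + 1, bounds[r + 1] + 1):
            res_of[i] = r + 1
    counts = {"C": 0, "O": 0, "H": 0}
    atoms = []
    for i in range(1, n + 1):
        e = heavy_elems[i - 1]
        counts[e] += 1
        rname = res_name if res_chunks == 1 else f"{res_name[:2]}{res_of[i]}"[:5]
        atoms.append(_atom(i, e, f"{e}{counts[e]}", res_index=res_of[i],
                           res_name=rname))
    bonds = [Bond(u, v) for u, v in edges]
    return MoleculeTopology(mol_name=name, atoms=atoms, bonds=bonds)


def make_molecule(recipe: str, seed: int = 0,
                  name: Optional[str] = None) -> MoleculeTopology:
    """Build a synthetic molecule topology.

    Recipes: ``water``, ``ion:<element>``, ``alkane:<k>``, ``benzene``,
    ``phenylacetic-acid``, ``asym``, ``lipid:<n_atoms>``,
    ``protein:<n_atoms>`` (multi-residue chain stand-in).
    """
    kind, _, arg = recipe.partition(":")
    name = name or kind.upper()[:8]
    if kind == "water":
        return _water(name)
    if kind == "ion":
        return _ion(name, arg or "K")
    if kind == "alkane":
        return _alkane(name, int(arg))
    if kind == "benzene":
        return _benzene(name)
    if kind == "phenylacetic-acid":
        return _phenylacetic_acid(name)
    if kind == "asym":
        return _asym(name)
    if kind == "lipid":
        return _heavy_tree(name, int(arg), seed, res_chunks=1, res_name="LIP")
    if kind == "protein":
        n = int(arg)
        return _heavy_tree(name, n, seed, res_chunks=max(2, n // 12),
                           res_name="PR")
    raise ValueError(f"unknown molecule recipe {recipe!r}")


def make_variant(
    top: MoleculeTopology, seed: int
) -> tuple[MoleculeTopology, tuple]:
    """Emulate the same molecule under a second force field: atoms randomly
    permuted, bonds re-indexed, atom/residue names deterministically
    mangled, residues re-chunked in the new order.

    Returns ``(variant, perm)`` where ``perm[i-1]`` is the variant index of
    source atom i.
    """
    rng = random.Random(seed)
    n = len(top.atoms)
    perm = list(range(1, n + 1))
    rng.shuffle(perm)  # perm[i-1] = new index of source atom i

    by_new = [None] * n
    for i, a in enumerate(top.atoms):
        by_new[perm[i] - 1] = a

    n_res = top.atoms[-1].res_index
    if n_res == 1:
        res_of = [1] * n
        res_names = {1: (top.atoms[0].res_name[:4] + "B")[:5]}
    else:
        bounds = [round(k * n / n_res) for k in range(n_res + 1)]
        res_of = [0] * n
        res_names = {}
        for r in range(n_res):
            for j in range(bounds[r], bounds[r + 1]):
                res_of[j] = r + 1
            res_names[r + 1] = f"R{r + 1:03d}"[:5]

    counts: dict[str, int] = {}
    new_atoms = []
    for j, a in enumerate(by_new):
        elem = infer_element(a.mass)
        counts[elem] = counts.get(elem, 0) + 1
        new_atoms.append(TopAtom(
            index=j + 1,
            type_name=a.type_name.upper() + "B",
            res_index=res_of[j],
            res_name=res_names[res_of[j]],
            atom_name=f"{elem}{counts[elem]}",
            charge=a.charge,
            mass=a.mass,
        ))

    new_bonds = sorted(
        Bond(min(perm[b.i - 1], perm[b.j - 1]), max(perm[b.i - 1], perm[b.j - 1]))
        for b in top.bonds
    )
    new_settles = None
    if top.settles is not None:
        s = top.settles
        new_settles = SettlesRecord(perm[s.ow - 1], s.d_oh, s.d_hh)
    new_posres = None
    if top.posres:
        new_posres = sorted(
            (PosResRecord(perm[r.index - 1], r.func, r.forces) for r in top.posres),
            key=lambda r: r.index,
        )
    variant = MoleculeTopology(
        mol_name=top.mol_name,
        atoms=new_atoms,
        bonds=new_bonds,
        settles=new_settles,
        posres=new_posres,
    )
    return variant, tuple(perm)


def make_system(
    comp: SystemComposition,
    tops: dict[str, MoleculeTopology],
    seed: int,
    velocities: bool = False,
    box_length: Optional[float] = None,
) -> CoordinateFile:
    """Pack molecules in composition order with seeded random coordinates.

    The box edge defaults to (N/100)^(1/3) nm — roughly the atom density of
    liquid water — and coordinates/velocities are quantized to the .gro
    printed precision so file round trips are exact.
    """
    total = comp.total_atoms(tops)
    rng = np.random.default_rng(seed)
    L = box_length if box_length is not None else round(max(2.0, (total / 100.0) ** (1 / 3)), 3)
    coords = np.round(rng.uniform(0.0, L, size=(total, 3)), 3).tolist()
    vels = (
        np.round(rng.normal(0.0, 0.5, size=(total, 3)), 4).tolist()
        if velocities else None
    )

    atoms: list[AtomRecord] = []
    append = atoms.append
    k = 0
    res_no = 0
    for name, count in comp.species:
        top = tops[name]
        n = len(top.atoms)
        names = [a.atom_name for a in top.atoms]
        rnames = [a.res_name for a in top.atoms]
        new_res = [True] + [
            top.atoms[t].res_index != top.atoms[t - 1].res_index
            for t in range(1, n)
        ]
        for _ in range(count):
            for t in range(n):
                if new_res[t]:
                    res_no += 1
                x, y, z = coords[k]
                vel = tuple(vels[k]) if vels is not None else None
                k += 1
                append(AtomRecord(res_no, rnames[t], names[t], k, x, y, z, vel))
    return CoordinateFile(
        title=f"synthetic packed system; seed={seed}",
        atoms=atoms,
        box=(L, L, L),
    )
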