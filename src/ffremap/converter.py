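"""Coordinate-file conversion between force fields.

The system is partitioned arithmetically into per-molecule slices from the
user-supplied composition (molecule names and counts in coordinate-file
order); residue labels in the source file are never trusted for
segmentation, since naming conventions differ across force fields — a
residue-number pattern inconsistent with the topology only logs a warning.
Each slice is then permuted by its molecule's atom mapping: the source
atom at position i lands at target position m(i) and takes its atom and
residue names from the target topology, while coordinates and velocities
travel untouched.  Atom numbers are renumbered 1..N and residue numbers
increment at every molecule start and at every residue boundary of the
target topology, so the output is directly usable with the new force
field's topology.  Back-conversion applies the inverted mappings and
restores the original atom order exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import CompositionError, MappingError
from .gro import AtomRecord, CoordinateFile
from .matcher import AtomMapping, invert_mapping
from .topology import MoleculeTopology, PosResRecord

__all__ = [
    "SystemComposition",
    "segment_system",
    "convert_system",
    "back_convert",
    "remap_restraints",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SystemComposition:
    """Ordered (molecule name, count) blocks of a coordinate file."""

    species: tuple  # ((mol_name, count), ...)

    def __post_init__(self) -> None:
        for name, count in self.species:
            if count < 1:
                raise CompositionError(f"{name}: molecule count must be >= 1")

    @classmethod
    def from_lists(cls, names: Sequence[str], counts: Sequence[int]) -> "SystemComposition":
        if len(names) != len(counts):
            raise CompositionError(
                f"{len(names)} molecule names but {len(counts)} counts"
            )
        return cls(tuple(zip(names, (int(c) for c in counts))))

    @property
    def n_molecules(self) -> int:
        return sum(c for _, c in self.species)

    def total_atoms(self, tops: Mapping[str, MoleculeTopology]) -> int:
        return sum(c * len(tops[n].atoms) for n, c in self.species)


def _check_total(cf: CoordinateFile, comp: SystemComposition,
                 tops: Mapping[str, MoleculeTopology]) -> None:
    for name, _ in comp.species:
        if name not in tops:
            raise MappingError(f"no topology supplied for molecule {name!r}")
    expected = comp.total_atoms(tops)
    if expected != len(cf.atoms):
        raise CompositionError(
            f"composition implies {expected} atoms but the coordinate file"
            f" holds {len(cf.atoms)}"
        )


def segment_system(
    cf: CoordinateFile,
    comp: SystemComposition,
    source_tops: Mapping[str, MoleculeTopology],
) -> list[tuple[str, int, int]]:
    """Partition the atom list into per-molecule (name, start, stop) slices
    (0-based, half-open), in composition order."""
    _check_total(cf, comp, source_tops)
    slices: list[tuple[str, int, int]] = []
    atoms = cf.atoms
    pos = 0
    warned: set[str] = set()
    for name, count in comp.species:
        top = source_tops[name]
        n = len(top.atoms)
        res_breaks = sum(
            1 for a, b in zip(top.atoms, top.atoms[1:])
            if b.res_index != a.res_index
        )
        for _ in range(count):
            sl = (name, pos, pos + n)
            slices.append(sl)
            if name not in warned:
                breaks = sum(
                    1 for k in range(pos + 1, pos + n)
                    if atoms[k].res_number != atoms[k - 1].res_number
                )
                if breaks != res_breaks:
                    warned.add(name)
                    log.warning(
                        "%s: residue numbering in the coordinate file (%d"
                        " boundaries) disagrees with the topology (%d); the"
                        " arithmetic segmentation is used regardless",
                        name, breaks, res_breaks,
                    )
            pos += n
    return slices


def convert_system(
    cf: CoordinateFile,
    comp: SystemComposition,
    mappings: Mapping[str, AtomMapping],
    target_tops: Mapping[str, MoleculeTopology],
) -> CoordinateFile:
    """Reorder, rename and renumber a whole system to the target force field."""
    _check_total(cf, comp, target_tops)
    plans: dict[str, tuple] = {}
    for name, _ in comp.species:
        if name not in mappings:
            raise MappingError(f"no atom mapping supplied for molecule {name!r}")
        top = target_tops[name]
        n = len(top.atoms)
        m = dict(mappings[name].pairs)
        if len(m) != n or set(m.values()) != set(range(1, n + 1)):
            raise MappingError(
                f"{name}: mapping covers {len(m)} atoms but the target"
                f" topology has {n}"
            )
        inv = [0] * n  # inv[t] = 0-based source position feeding target slot t+1
        for s, t in m.items():
            inv[t - 1] = s - 1
        atom_names = [a.atom_name for a in top.atoms]
        res_names = [a.res_name for a in top.atoms]
        # new-residue flag per target slot (first slot always starts one)
        new_res = [True] + [
            top.atoms[t].res_index != top.atoms[t - 1].res_index
            for t in range(1, n)
        ]
        plans[name] = (n, inv, atom_names, res_names, new_res)

    out: list[AtomRecord] = []
    append = out.append
    atoms = cf.atoms
    pos = 0
    atom_no = 0
    res_no = 0
    for name, count in comp.species:
        n, inv, atom_names, res_names, new_res = plans[name]
        for _ in range(count):
            for t in range(n):
                src = atoms[pos + inv[t]]
                if new_res[t]:
                    res_no += 1
                atom_no += 1
                append(AtomRecord(
                    res_no, res_names[t], atom_names[t], atom_no,
                    src.x, src.y, src.z, src.vel,
                ))
            pos += n
    return CoordinateFile(
        title=f"{cf.title} (force-field converted)",
        atoms=out,
        box=cf.box,
    )


def back_convert(
    cf_converted: CoordinateFile,
    comp: SystemComposition,
    mappings: Mapping[str, AtomMapping],
    source_tops: Mapping[str, MoleculeTopology],
) -> CoordinateFile:
    """Invert the conversion: composed with :func:`convert_system` it
    restores the original atom order and coordinates exactly."""
    inverted = {name: invert_mapping(m) for name, m in mappings.items()}
    return convert_system(cf_converted, comp, inverted, source_tops)


def remap_restraints(
    posres: Sequence[PosResRecord], m: AtomMapping
) -> list[PosResRecord]:
    """Renumber position-restraint atom indices to the target ordering;
    force constants are untouched; output sorted by new index."""
    d = dict(m.pairs)
    out: list[PosResRecord] = []
    for r in posres:
        if r.index not in d:
            raise MappingError(
                f"restrained atom index {r.index} outside the mapping (1..{len(d)})"
            )
        out.append(PosResRecord(d[r.index], r.func, r.forces))
    return sorted(out, key=lambda r: r.index)
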