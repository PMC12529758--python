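"""GROMACS included-topology (.itp) parsing and element inference.

An ITP file describes one molecule type: its ``[ moleculetype ]`` header,
the ``[ atoms ]`` block (one line per atom, with partial charge and mass),
and connectivity as either a ``[ bonds ]`` block or — for rigid 3-site
waters constrained by SETTLE — a ``[ settles ]`` block.  Angles, dihedrals,
pairs and exclusions carry no extra connectivity information for our
purposes and are ignored.  ``[ position_restraints ]`` blocks are captured
so restraint indices can be renumbered after conversion.

Chemical elements are inferred from the per-atom mass column: the closest
standard atomic weight wins, provided it lies within a tolerance
(default 0.3 amu).  Virtual sites and repartitioned heavy hydrogens fall
outside every window and are rejected, by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

from .errors import ElementError, TopologyError, UnsupportedDialectError

__all__ = [
    "TopAtom",
    "Bond",
    "SettlesRecord",
    "PosResRecord",
    "MoleculeTopology",
    "ElementTable",
    "DEFAULT_ELEMENTS",
    "parse_itp",
    "parse_posres",
    "write_itp",
    "infer_element",
    "atoms_per_molecule",
]


class TopAtom(NamedTuple):
    """One line of an ``[ atoms ]`` block."""

    index: int          # 1-based atom number within the molecule
    type_name: str      # force-field atom type
    res_index: int      # 1-based residue index within the molecule
    res_name: str
    atom_name: str
    charge: float       # partial charge (e); informational
    mass: float         # atomic mass (amu); drives element inference


class Bond(NamedTuple):
    """An unordered connectivity edge between two atoms (1-based indices)."""

    i: int
    j: int


class SettlesRecord(NamedTuple):
    """SETTLE constraint block of a rigid 3-site water.

    ``ow`` is the atom index listed first in the block (the oxygen); the
    constraint distances are informational only.
    """

    ow: int
    d_oh: float
    d_hh: float


class PosResRecord(NamedTuple):
    """One ``[ position_restraints ]`` line: atom index, function type,
    force constants (kJ mol^-1 nm^-2, untouched by remapping)."""

    index: int
    func: int
    forces: tuple


@dataclass
class MoleculeTopology:
    """One molecule type's atoms, connectivity and residue structure."""

    mol_name: str
    atoms: list[TopAtom]
    bonds: list[Bond] = field(default_factory=list)
    settles: Optional[SettlesRecord] = None
    posres: Optional[list[PosResRecord]] = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def atoms_per_molecule(top: MoleculeTopology) -> int:
    """Number of atoms in one molecule of this type."""
    return len(top.atoms)


# Standard atomic weights (amu), elements 1-86 (H through Rn).
# Conventional values to the precision force-field mass columns carry.
_ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Tc": 97.0, "Ru": 101.07, "Rh": 102.91,
    "Pd": 106.42, "Ag": 107.87, "Cd": 112.41, "In": 114.82, "Sn": 118.71,
    "Sb": 121.76, "Te": 127.60, "I": 126.90, "Xe": 131.29, "Cs": 132.91,
    "Ba": 137.33, "La": 138.91, "Ce": 140.12, "Pr": 140.91, "Nd": 144.24,
    "Pm": 145.0, "Sm": 150.36, "Eu": 151.96, "Gd": 157.25, "Tb": 158.93,
    "Dy": 162.50, "Ho": 164.93, "Er": 167.26, "Tm": 168.93, "Yb": 173.05,
    "Lu": 174.97, "Hf": 178.49, "Ta": 180.95, "W": 183.84, "Re": 186.21,
    "Os": 190.23, "Ir": 192.22, "Pt": 195.08, "Au": 196.97, "Hg": 200.59,
    "Tl": 204.38, "Pb": 207.2, "Bi": 208.98, "Po": 209.0, "At": 210.0,
    "Rn": 222.0,
}


@dataclass(frozen=True)
class ElementTable:
    """Element symbol -> standard atomic mass, with a matching tolerance."""

    masses: dict[str, float]
    tolerance: float = 0.3

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("element masses must be strictly positive")


DEFAULT_ELEMENTS = ElementTable(masses=_ATOMIC_WEIGHTS)

_TIE_EPS = 1e-9


def infer_element(mass: float, table: ElementTable = DEFAULT_ELEMENTS) -> str:
    """Resolve an atomic mass to the element with the closest standard
    atomic weight.

    Raises :class:`ElementError` if no tabulated mass lies within the
    table's tolerance of ``mass`` (e.g. virtual sites with mass 0 handled
    upstream, deuterium 2.014, repartitioned hydrogens), or if two elements
    tie exactly — a silent coin flip could mislabel graph nodes.
    """
    if mass <= 0:
        raise ElementError(f"non-positive atomic mass {mass!r}")
    best_sym, best_d = None, float("inf")
    second_d = float("inf")
    for sym, m in table.masses.items():
        d = abs(mass - m)
        if d < best_d:
            best_sym, best_d, second_d = sym, d, best_d
        elif d < second_d:
            second_d = d
    if best_d > table.tolerance + _TIE_EPS:
        raise ElementError(
            f"no element within {table.tolerance} amu of mass {mass}"
            f" (closest: {best_sym} at {best_d:.4g} amu)"
        )
    if second_d - best_d <= _TIE_EPS:
        raise ElementError(f"ambiguous element for mass {mass}: exact tie")
    return best_sym  # type: ignore[return-value]


# --- ITP parsing -----------------------------------------------------------

_KNOWN_SECTIONS = {
    "moleculetype", "atoms", "bonds", "settles", "position_restraints",
}


def _strip_comment(line: str) -> str:
    return line.split(";", 1)[0]


def parse_itp(path) -> MoleculeTopology:
    """Parse a single-molecule GROMACS .itp file.

    Supported dialect: exactly one ``[ moleculetype ]`` and one
    ``[ atoms ]`` section; ``;`` starts a comment anywhere; preprocessor
    directives (``#include``, ``#ifdef``, ...) are rejected.  Sections other
    than moleculetype/atoms/bonds/settles/position_restraints are ignored.
    """
    path = Path(path)
    mol_name: Optional[str] = None
    atoms: list[TopAtom] = []
    bonds: list[Bond] = []
    settles: Optional[SettlesRecord] = None
    posres: list[PosResRecord] = []
    seen: set[str] = set()
    section: Optional[str] = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = _strip_comment(raw).strip()
            if not line:
                continue
            if line.startswith("#"):
                raise UnsupportedDialectError(
                    f"{path}:{lineno}: preprocessor directive {line.split()[0]!r}"
                    " is not supported; supply one plain ITP per molecule type"
                )
            if line.startswith("["):
                name = line.strip("[] \t").lower()
                if name in _KNOWN_SECTIONS:
                    if name in seen:
                        raise UnsupportedDialectError(
                            f"{path}:{lineno}: duplicate [ {name} ] section"
                        )
                    seen.add(name)
                    section = name
                else:
                    section = None  # pairs, angles, dihedrals, exclusions...
                continue

            if section == "moleculetype":
                if mol_name is not None:
                    raise UnsupportedDialectError(
                        f"{path}:{lineno}: more than one moleculetype entry;"
                        " only single-molecule ITP files are supported"
                    )
                mol_name = line.split()[0]
            elif section == "atoms":
                fields = line.split()
                if len(fields) < 8:
                    raise TopologyError(
                        f"{path}:{lineno}: mass unavailable — the atoms block"
                        " must carry the per-atom mass in column 8"
                    )
                try:
                    atoms.append(TopAtom(
                        index=int(fields[0]),
                        type_name=fields[1],
                        res_index=int(fields[2]),
                        res_name=fields[3],
                        atom_name=fields[4],
                        charge=float(fields[6]),
                        mass=float(fields[7]),
                    ))
                except ValueError as exc:
                    raise TopologyError(f"{path}:{lineno}: bad atoms line: {exc}")
            elif section == "bonds":
                fields = line.split()
                if len(fields) < 2:
                    raise TopologyError(f"{path}:{lineno}: bad bonds line")
                try:
                    bonds.append(Bond(int(fields[0]), int(fields[1])))
                except ValueError as exc:
                    raise TopologyError(f"{path}:{lineno}: bad bonds line: {exc}")
            elif section == "settles":
                fields = line.split()
                if len(fields) < 4:
                    raise TopologyError(f"{path}:{lineno}: bad settles line")
                try:
                    settles = SettlesRecord(
                        int(fields[0]), float(fields[2]), float(fields[3]))
                except ValueError as exc:
                    raise TopologyError(f"{path}:{lineno}: bad settles line: {exc}")
            elif section == "position_restraints":
                fields = line.split()
                if len(fields) < 2:
                    raise TopologyError(f"{path}:{lineno}: bad restraint line")
                try:
                    posres.append(PosResRecord(
                        int(fields[0]), int(fields[1]),
                        tuple(float(f) for f in fields[2:])))
                except ValueError as exc:
                    raise TopologyError(f"{path}:{lineno}: bad restraint line: {exc}")

    if mol_name is None:
        raise TopologyError(f"{path}: missing [ moleculetype ] section")
    if "atoms" not in seen:
        raise TopologyError(f"{path}: missing [ atoms ] section")

    top = MoleculeTopology(
        mol_name=mol_name, atoms=atoms, bonds=bonds,
        settles=settles, posres=posres or None,
    )
    _validate_topology(top, str(path))
    return top


def _validate_topology(top: MoleculeTopology, where: str) -> None:
    n = len(top.atoms)
    if n == 0:
        raise TopologyError(f"{where}: empty atoms block")
    indices = [a.index for a in top.atoms]
    if indices != list(range(1, n + 1)):
        raise TopologyError(
            f"{where}: atom indices must be exactly 1..{n} in order"
        )
    for a in top.atoms:
        if a.mass <= 0:
            raise TopologyError(f"{where}: atom {a.index} has non-positive mass")
        if not a.atom_name or not a.res_name:
            raise TopologyError(f"{where}: atom {a.index} has an empty name")
    res_seq = [a.res_index for a in top.atoms]
    if any(b < a for a, b in zip(res_seq, res_seq[1:])) or res_seq[0] < 1:
        raise TopologyError(f"{where}: residue indices must be non-decreasing from 1")
    seen_bonds: set[tuple[int, int]] = set()
    for b in top.bonds:
        if b.i == b.j:
            raise TopologyError(f"{where}: self-bond on atom {b.i}")
        if not (1 <= b.i <= n and 1 <= b.j <= n):
            raise TopologyError(f"{where}: bond ({b.i},{b.j}) out of range 1..{n}")
        key = (min(b.i, b.j), max(b.i, b.j))
        if key in seen_bonds:
            raise TopologyError(f"{where}: duplicate bond {key}")
        seen_bonds.add(key)
    if top.settles is not None:
        if n != 3:
            raise TopologyError(
                f"{where}: a settles block requires exactly 3 atoms, found {n}"
            )
        if not 1 <= top.settles.ow <= n:
            raise TopologyError(f"{where}: settles index {top.settles.ow} out of range")
    if n > 1 and not top.bonds and top.settles is None:
        raise TopologyError(
            f"{where}: molecule with {n} atoms has neither bonds nor settles"
        )
    if top.posres:
        for r in top.posres:
            if not 1 <= r.index <= n:
                raise TopologyError(
                    f"{where}: position restraint on atom {r.index} out of range"
                )


def parse_posres(path) -> list[PosResRecord]:
    """Read a standalone position-restraint .itp (only the
    ``[ position_restraints ]`` block is required)."""
    path = Path(path)
    records: list[PosResRecord] = []
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = _strip_comment(raw).strip()
            if not line:
                continue
            if line.startswith("#"):
                raise UnsupportedDialectError(
                    f"{path}:{lineno}: preprocessor directives are not supported"
                )
            if line.startswith("["):
                section = line.strip("[] \t").lower()
                continue
            if section == "position_restraints":
                fields = line.split()
                try:
                    records.append(PosResRecord(
                        int(fields[0]), int(fields[1]),
                        tuple(float(f) for f in fields[2:])))
                except (ValueError, IndexError) as exc:
                    raise TopologyError(f"{path}:{lineno}: bad restraint line: {exc}")
    if not records:
        raise TopologyError(f"{path}: no [ position_restraints ] entries found")
    return records


def write_itp(top: MoleculeTopology, path) -> None:
    """Serialize a topology back to .itp text (fixture round trips)."""
    _validate_topology(top, "write_itp")
    lines = ["[ moleculetype ]", "; name  nrexcl", f"{top.mol_name}  3", ""]
    lines.append("[ atoms ]")
    lines.append(";  nr type resnr residue atom cgnr charge mass")
    for a in top.atoms:
        lines.append(
            f"{a.index:6d} {a.type_name:>6s} {a.res_index:5d} {a.res_name:>6s}"
            f" {a.atom_name:>6s} {a.index:5d} {a.charge:9.4f} {a.mass:10.4f}"
        )
    if top.bonds:
        lines += ["", "[ bonds ]", ";  i    j  funct"]
        for b in top.bonds:
            lines.append(f"{b.i:6d} {b.j:6d}     1")
    if top.settles is not None:
        s = top.settles
        lines += ["", "[ settles ]", "; OW  funct  doh  dhh",
                  f"{s.ow:6d}     1 {s.d_oh:.5f} {s.d_hh:.5f}"]
    if top.posres:
        lines += ["", "[ position_restraints ]", ";  i funct  fc"]
        for r in top.posres:
            fc = " ".join(f"{f:g}" for f in r.forces)
            lines.append(f"{r.index:6d} {r.func:5d} {fc}")
    Path(path).write_text("\n".join(lines) + "\n")
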