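"""Gromos87 (.gro) coordinate file reader/writer.

The format is fixed-column: a free-text title line, the atom count, one
line per atom (residue number %5d, residue name %-5s, atom name %5s, atom
number %5d, x/y/z in %8.3f nm, optionally vx/vy/vz in %8.4f nm/ps), and a
final box-vector line of 3 or 9 floats.  Velocity presence is detected
from the data width of the atom lines.  Display numbers wrap modulo
100000 to fit their 5-column fields, exactly as GROMACS prints them.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional

from .errors import GroFormatError

__all__ = ["AtomRecord", "CoordinateFile", "read_gro", "write_gro"]

log = logging.getLogger(__name__)


class AtomRecord(NamedTuple):
    res_number: int
    res_name: str
    atom_name: str
    atom_number: int
    x: float
    y: float
    z: float
    vel: Optional[tuple] = None  # (vx, vy, vz) or None


@dataclass
class CoordinateFile:
    title: str
    atoms: list[AtomRecord]
    box: tuple

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def has_velocities(self) -> bool:
        return bool(self.atoms) and self.atoms[0].vel is not None


def read_gro(path) -> CoordinateFile:
    """Parse a .gro file by fixed column positions."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) < 3:
        raise GroFormatError(f"{path}: truncated file ({len(lines)} lines)")
    title = lines[0]
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise GroFormatError(f"{path}:2: atom count is not an integer")
    if len(lines) != n + 3:
        raise GroFormatError(
            f"{path}: header declares {n} atoms but the file holds"
            f" {len(lines) - 3} atom lines"
        )

    has_vel = n > 0 and len(lines[2].rstrip()) >= 68
    intern = sys.intern
    atoms: list[AtomRecord] = []
    append = atoms.append
    for k in range(n):
        line = lines[2 + k]
        try:
            res_number = int(line[0:5])
            res_name = intern(line[5:10].strip())
            atom_name = intern(line[10:15].strip())
            atom_number = int(line[15:20])
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
            vel = (
                (float(line[44:52]), float(line[52:60]), float(line[60:68]))
                if has_vel else None
            )
        except ValueError as exc:
            raise GroFormatError(f"{path}:{3 + k}: malformed atom line: {exc}")
        if not res_name or not atom_name:
            raise GroFormatError(f"{path}:{3 + k}: empty residue or atom name")
        append(AtomRecord(res_number, res_name, atom_name, atom_number, x, y, z, vel))

    box_fields = lines[n + 2].split()
    try:
        box = tuple(float(f) for f in box_fields)
    except ValueError:
        raise GroFormatError(f"{path}:{n + 3}: malformed box line")
    if len(box) not in (3, 9):
        raise GroFormatError(
            f"{path}:{n + 3}: box line must hold 3 or 9 values, found {len(box)}"
        )
    return CoordinateFile(title=title, atoms=atoms, box=box)


def write_gro(cf: CoordinateFile, path) -> None:
    """Write fixed-format .gro; ``read_gro(write_gro(cf)) == cf`` up to
    the printed precision (3 decimals coordinates, 4 velocities)."""
    path = Path(path)
    warned: set[str] = set()
    with open(path, "w") as fh:
        out = [f"{cf.title}\n", f"{len(cf.atoms):5d}\n"]
        for rec in cf.atoms:
            rn, an = rec.res_name, rec.atom_name
            for name in (rn, an):
                if len(name) > 5 and name not in warned:
                    warned.add(name)
                    log.warning("name %r longer than 5 characters; truncated", name)
            line = (
                f"{rec.res_number % 100000:5d}{rn:<5.5s}{an:>5.5s}"
                f"{rec.atom_number % 100000:5d}"
                f"{rec.x:8.3f}{rec.y:8.3f}{rec.z:8.3f}"
            )
            if rec.vel is not None:
                vx, vy, vz = rec.vel
                line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
            out.append(line + "\n")
            if len(out) >= 200000:
                fh.writelines(out)
                out = []
        out.append("".join(f"{v:10.5f}" for v in cf.box) + "\n")
        fh.writelines(out)
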