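"""On-disk mapping database.

A mapping directory holds one ``<molecule>.map.csv`` per molecule type
(header ``source,target``, one 1-based index pair per atom, sorted by
source) and, by convention, the target force field's ``<molecule>.itp``
files, which the converter picks up automatically for renaming.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

from .errors import MappingError, MappingNotFoundError
from .matcher import AtomMapping
from .topology import MoleculeTopology, parse_itp

__all__ = [
    "mapping_path",
    "save_mapping",
    "load_mapping",
    "locate_target_itp",
]


def mapping_path(name: str, directory) -> Path:
    return Path(directory) / f"{name}.map.csv"


def save_mapping(m: AtomMapping, directory, overwrite: bool = False) -> Path:
    """Write ``<mol_name>.map.csv`` into the mapping directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = mapping_path(m.mol_name, directory)
    if path.exists() and not overwrite:
        raise MappingError(
            f"{path} already exists; pass overwrite to replace it"
        )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target"])
        for s, t in sorted(m.pairs):
            writer.writerow([s, t])
    return path


def load_mapping(name: str, directory) -> AtomMapping:
    """Load and invariant-check a stored mapping."""
    path = mapping_path(name, directory)
    if not path.exists():
        raise MappingNotFoundError(
            f"no mapping for {name!r} at {path}; run ffmap for this molecule"
            " and store the result in the mapping directory"
        )
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        raise MappingError(f"{path}: empty mapping file")
    pairs: dict[int, int] = {}
    for rn, row in enumerate(rows[1:], 2):
        try:
            s, t = int(row[0]), int(row[1])
        except (ValueError, IndexError):
            raise MappingError(f"{path}: row {rn} is not an index pair")
        if s in pairs:
            raise MappingError(f"{path}: duplicate source index {s}")
        pairs[s] = t
    n = len(pairs)
    if set(pairs) != set(range(1, n + 1)) or set(pairs.values()) != set(range(1, n + 1)):
        raise MappingError(f"{path}: rows do not form a bijection on 1..{n}")
    return AtomMapping.from_dict(name, pairs)


def locate_target_itp(name: str, directory) -> Optional[MoleculeTopology]:
    """Load ``<name>.itp`` from the mapping directory if present.

    Returns None when the file is absent — the caller should then ask the
    user for a path; a present but unparseable file raises."""
    path = Path(directory) / f"{name}.itp"
    if not path.exists():
        return None
    return parse_itp(path)
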