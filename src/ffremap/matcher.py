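"""Deterministic element-preserving graph isomorphism.

Two topologies describe the same molecule when their element-labeled
graphs are isomorphic; the mapping returned here is the permutation that
reorders the coordinate file.  The search is a VF2-style backtracking
matcher: a partial mapping is extended one node pair at a time, and a
candidate pair is accepted only if it passes feasibility checks — equal
element labels (semantic), consistency of edges to already-mapped nodes in
both directions, and a one-hop look-ahead comparing the element counts of
unmapped neighbors (syntactic).  If the graphs are isomorphic the search
is guaranteed to find a mapping; the first mapping found under a fixed,
fully deterministic candidate order is returned, so identical inputs
always yield identical output.  Several valid mappings can exist when the
molecule has automorphisms (e.g. equivalent hydrogens on one carbon); any
of them yields a physically identical reordering.

Optional atom-name equivalence constraints pin selected atoms of one
force field to named atoms of the other; unconstrained atoms are mapped
by element and connectivity alone.

A brute-force permutation oracle (small molecules only) backs the test
suite.
"""

from __future__ import annotations

import csv
import itertools
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from .errors import ConstraintError, MappingError, MatchTimeout, NotIsomorphicError
from .molgraph import MolecularGraph, degree_histogram

__all__ = [
    "AtomMapping",
    "NamingConstraints",
    "load_naming_csv",
    "find_isomorphism",
    "brute_force_isomorphism",
    "invert_mapping",
    "validate_mapping",
]


@dataclass(frozen=True)
class AtomMapping:
    """Bijection source atom index -> target atom index over 1..n."""

    mol_name: str
    pairs: tuple  # ((source, target), ...) sorted by source

    @classmethod
    def from_dict(cls, mol_name: str, d: dict[int, int]) -> "AtomMapping":
        return cls(mol_name, tuple(sorted(d.items())))

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def n(self) -> int:
        return len(self.pairs)

    def apply(self, i: int) -> int:
        d = dict(self.pairs)
        return d[i]


@dataclass(frozen=True)
class NamingConstraints:
    """Atom-name equivalences: (name under force field 1, name under 2)."""

    pairs: tuple  # ((name1, name2), ...)
    header: Optional[tuple] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ConstraintError("naming constraints supplied but empty")
        col1 = [a for a, _ in self.pairs]
        col2 = [b for _, b in self.pairs]
        for col, label in ((col1, "first"), (col2, "second")):
            dupes = [k for k, c in Counter(col).items() if c > 1]
            if dupes:
                raise ConstraintError(
                    f"duplicate names in the {label} CSV column: {dupes};"
                    " make the names temporarily unique before mapping"
                )


def load_naming_csv(path) -> NamingConstraints:
    """Read a two-column atom-name equivalence CSV.  The first row is the
    mandatory header; every following row pins one atom pair."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(f.strip() for f in row)]
    if len(rows) < 2:
        raise ConstraintError(
            f"{path}: need a header row plus at least one name pair"
        )
    for rn, row in enumerate(rows, 1):
        if len(row) < 2:
            raise ConstraintError(f"{path}: row {rn} has fewer than 2 columns")
    header = (rows[0][0].strip(), rows[0][1].strip())
    pairs = tuple((r[0].strip(), r[1].strip()) for r in rows[1:])
    return NamingConstraints(pairs=pairs, header=header)


def _name_index(g: MolecularGraph, name: str, side: str) -> Optional[int]:
    hits = [i for i in range(1, g.n + 1) if g.names[i - 1] == name]
    if len(hits) > 1:
        raise ConstraintError(
            f"atom name {name!r} occurs {len(hits)} times in the {side} topology;"
            " constrained names must be unique — uniquify them temporarily"
        )
    return hits[0] if hits else None


def _bind_constraints(
    g1: MolecularGraph, g2: MolecularGraph, constraints: NamingConstraints
) -> dict[int, int]:
    """Resolve name pairs to a pinned index map, validating before search."""
    if constraints.header is not None:
        h1, h2 = constraints.header
        if _name_index(g1, h1, "source") and _name_index(g2, h2, "target"):
            raise ConstraintError(
                "the naming CSV appears to lack a header: its first row"
                f" ({h1!r},{h2!r}) names real atoms in both topologies"
            )
    pinned: dict[int, int] = {}
    for a, b in constraints.pairs:
        u = _name_index(g1, a, "source")
        v = _name_index(g2, b, "target")
        if u is None or v is None:
            missing = a if u is None else b
            raise ConstraintError(
                f"constrained atom name {missing!r} not found in its topology"
            )
        if g1.element(u) != g2.element(v):
            raise ConstraintError(
                f"constraint pins {a!r} ({g1.element(u)}) to {b!r}"
                f" ({g2.element(v)}): different elements"
            )
        pinned[u] = v
    return pinned


def _precheck(g1: MolecularGraph, g2: MolecularGraph) -> None:
    if g1.n != g2.n:
        raise NotIsomorphicError(
            f"the graphs are not isomorphic: {g1.n} vs {g2.n} atoms"
        )
    if g1.element_multiset() != g2.element_multiset():
        raise NotIsomorphicError(
            "the graphs are not isomorphic: element compositions differ"
            f" ({dict(g1.element_multiset())} vs {dict(g2.element_multiset())})"
        )
    if degree_histogram(g1) != degree_histogram(g2):
        raise NotIsomorphicError(
            "the graphs are not isomorphic: connectivity (degree histogram) differs"
        )


def find_isomorphism(
    g1: MolecularGraph,
    g2: MolecularGraph,
    constraints: Optional[NamingConstraints] = None,
    mol_name: str = "molecule",
    wall_limit: Optional[float] = None,
) -> AtomMapping:
    """Return the first element-preserving isomorphism g1 -> g2 found under
    a fixed deterministic search order.

    Search order: the seed node is the g1 atom of the rarest element, then
    highest degree, then lowest index; thereafter the frontier node most
    connected to the mapped set (ties: higher degree, lower index) is
    extended next, and target candidates are tried in ascending index.

    There is no timeout by default; ``wall_limit`` (seconds) optionally
    aborts long searches with :class:`~ffremap.errors.MatchTimeout` — a run
    of many minutes on a molecular graph generally indicates a protonation
    mismatch between the two topologies rather than a hard instance.

    Raises :class:`~ffremap.errors.NotIsomorphicError` when no isomorphism
    exists, :class:`~ffremap.errors.ConstraintError` for invalid pins.
    """
    pinned = _bind_constraints(g1, g2, constraints) if constraints else {}
    _precheck(g1, g2)

    n = g1.n
    adj1, adj2 = g1.adj, g2.adj
    el1, el2 = g1.elements, g2.elements
    pinned_targets = set(pinned.values())

    core1: dict[int, int] = {}
    core2: dict[int, int] = {}

    el_counts = Counter(el1)

    def choose_next() -> int:
        frontier = [
            u for u in range(1, n + 1)
            if u not in core1 and any(w in core1 for w in adj1[u])
        ]
        if frontier:
            return max(
                frontier,
                key=lambda u: (
                    sum(1 for w in adj1[u] if w in core1), len(adj1[u]), -u
                ),
            )
        # seed (connected graphs: only at the start)
        rest = [u for u in range(1, n + 1) if u not in core1]
        return min(rest, key=lambda u: (el_counts[el1[u - 1]], -len(adj1[u]), u))

    def candidates(u: int) -> Iterator[int]:
        eu = el1[u - 1]
        deg_u = len(adj1[u])
        pin = pinned.get(u)
        pool = (pin,) if pin is not None else range(1, n + 1)
        for v in pool:
            if v in core2 or el2[v - 1] != eu or len(adj2[v]) != deg_u:
                continue
            if pin is None and v in pinned_targets:
                continue
            # edges to the mapped set must correspond exactly (both ways)
            mapped_imgs = {core1[w] for w in adj1[u] if w in core1}
            v_mapped = {x for x in adj2[v] if x in core2}
            if mapped_imgs != v_mapped:
                continue
            # 1-hop look-ahead: unmapped neighborhoods must agree by element
            la1 = Counter(el1[w - 1] for w in adj1[u] if w not in core1)
            la2 = Counter(el2[x - 1] for x in adj2[v] if x not in core2)
            if la1 != la2:
                continue
            yield v

    start = time.monotonic() if wall_limit is not None else 0.0
    steps = 0
    u0 = choose_next()
    stack: list[tuple[int, Iterator[int]]] = [(u0, candidates(u0))]
    while stack:
        if wall_limit is not None:
            steps += 1
            if steps % 512 == 1 and time.monotonic() - start > wall_limit:
                raise MatchTimeout(
                    f"{mol_name}: isomorphism search exceeded {wall_limit} s;"
                    " a very long search generally indicates a protonation"
                    " mismatch between the two topologies"
                )
        u, it = stack[-1]
        v = next(it, None)
        if v is not None:
            core1[u] = v
            core2[v] = u
            if len(core1) == n:
                return AtomMapping.from_dict(mol_name, core1)
            nu = choose_next()
            stack.append((nu, candidates(nu)))
        else:
            stack.pop()
            if stack:
                pu = stack[-1][0]
                pv = core1.pop(pu)
                del core2[pv]
    raise NotIsomorphicError(
        "the graphs are not isomorphic: search exhausted without a mapping"
        + (" satisfying the naming constraints" if constraints else "")
    )


_BRUTE_FORCE_LIMIT = 10


def brute_force_isomorphism(
    g1: MolecularGraph,
    g2: MolecularGraph,
    constraints: Optional[NamingConstraints] = None,
    mol_name: str = "molecule",
) -> Optional[AtomMapping]:
    """Exhaustive oracle: enumerate all element-compatible assignments and
    return the first valid isomorphism, or None.  Refuses n > 10."""
    if g1.n > _BRUTE_FORCE_LIMIT or g2.n > _BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute-force search limited to {_BRUTE_FORCE_LIMIT} atoms"
        )
    if g1.n != g2.n or g1.element_multiset() != g2.element_multiset():
        return None
    pinned = _bind_constraints(g1, g2, constraints) if constraints else {}

    by_el1: dict[str, list[int]] = {}
    by_el2: dict[str, list[int]] = {}
    for i in range(1, g1.n + 1):
        by_el1.setdefault(g1.element(i), []).append(i)
        by_el2.setdefault(g2.element(i), []).append(i)

    symbols = sorted(by_el1)
    perm_iters = [itertools.permutations(by_el2[s]) for s in symbols]
    for combo in itertools.product(*perm_iters):
        mapping: dict[int, int] = {}
        for s, perm in zip(symbols, combo):
            mapping.update(zip(by_el1[s], perm))
        if any(mapping[u] != v for u, v in pinned.items()):
            continue
        image = {(min(mapping[i], mapping[j]), max(mapping[i], mapping[j]))
                 for i, j in g1.edges}
        if image == set(g2.edges):
            return AtomMapping.from_dict(mol_name, mapping)
    return None


def invert_mapping(m: AtomMapping) -> AtomMapping:
    """Swap the two columns and resort by the (new) source index."""
    return AtomMapping.from_dict(m.mol_name, {t: s for s, t in m.pairs})


def validate_mapping(
    m: AtomMapping, g1: MolecularGraph, g2: MolecularGraph
) -> None:
    """Check bijection, element preservation and exact adjacency
    correspondence; raise :class:`~ffremap.errors.MappingError` otherwise."""
    d = dict(m.pairs)
    n = g1.n
    if g2.n != n or len(d) != n:
        raise MappingError(f"{m.mol_name}: mapping size {len(d)} != {n} atoms")
    if set(d) != set(range(1, n + 1)) or set(d.values()) != set(range(1, n + 1)):
        raise MappingError(f"{m.mol_name}: mapping is not a bijection on 1..{n}")
    for s, t in d.items():
        if g1.element(s) != g2.element(t):
            raise MappingError(
                f"{m.mol_name}: atom {s} ({g1.element(s)}) mapped to"
                f" {t} ({g2.element(t)})"
            )
    image = {(min(d[i], d[j]), max(d[i], d[j])) for i, j in g1.edges}
    if image != set(g2.edges):
        raise MappingError(f"{m.mol_name}: mapping does not preserve bonds")
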