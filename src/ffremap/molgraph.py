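"""Element-labeled molecular graphs.

A molecule becomes a connected graph: one node per atom, labeled with the
chemical element inferred from its mass (atom names ride along for the
consistent-naming feature but do not label nodes), one edge per bond.
Rigid waters without a bonds block contribute the two O-H edges implied by
their settles block; no H-H edge is added, so a SETTLE-based water matches
a two-bond water topology from another force field.
"""

from __future__ import annotations

from collections import Counter

from .errors import GraphError
from .topology import DEFAULT_ELEMENTS, ElementTable, MoleculeTopology, infer_element

__all__ = ["MolecularGraph", "build_graph", "degree_histogram"]


class MolecularGraph:
    """Connected graph with 1-based node indices and element labels."""

    __slots__ = ("n", "elements", "names", "edges", "adj")

    def __init__(self, n: int, elements: tuple, names: tuple, edges: frozenset):
        self.n = n
        self.elements = elements  # elements[i-1] = symbol of atom i
        self.names = names        # names[i-1] = atom name of atom i
        self.edges = edges        # frozenset of (i, j) with i < j
        adj: dict[int, set[int]] = {i: set() for i in range(1, n + 1)}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        self.adj = {i: frozenset(s) for i, s in adj.items()}

    def element(self, i: int) -> str:
        return self.elements[i - 1]

    def degree(self, i: int) -> int:
        return len(self.adj[i])

    def element_multiset(self) -> Counter:
        return Counter(self.elements)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MolecularGraph)
            and self.n == other.n
            and self.elements == other.elements
            and self.names == other.names
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"MolecularGraph(n={self.n}, edges={len(self.edges)})"


def build_graph(
    top: MoleculeTopology, table: ElementTable = DEFAULT_ELEMENTS
) -> MolecularGraph:
    """Build the element-labeled graph of one molecule.

    Raises :class:`~ffremap.errors.ElementError` when a mass resolves to no
    element and :class:`~ffremap.errors.GraphError` when the result is not
    one connected molecule.
    """
    n = len(top.atoms)
    elements = tuple(infer_element(a.mass, table) for a in top.atoms)
    names = tuple(a.atom_name for a in top.atoms)

    edge_set: set[tuple[int, int]] = set()
    if top.bonds:
        for b in top.bonds:
            edge_set.add((min(b.i, b.j), max(b.i, b.j)))
    elif top.settles is not None:
        ow = top.settles.ow
        for h in range(1, n + 1):
            if h != ow:
                edge_set.add((min(ow, h), max(ow, h)))
    elif n > 1:
        raise GraphError(
            f"{top.mol_name}: no bonds or settles — cannot build connectivity"
        )

    g = MolecularGraph(n, elements, names, frozenset(edge_set))
    # connectivity check (BFS from node 1)
    seen = {1}
    stack = [1]
    while stack:
        u = stack.pop()
        for v in g.adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) != n:
        raise GraphError(
            f"{top.mol_name}: graph is disconnected ({len(seen)} of {n} atoms"
            " reachable) — not a single molecule"
        )
    return g


def degree_histogram(g: MolecularGraph) -> dict[int, int]:
    """Map node degree -> number of nodes with that degree."""
    return dict(Counter(len(g.adj[i]) for i in range(1, g.n + 1)))
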