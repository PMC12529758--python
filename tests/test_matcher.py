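"""Isomorphism search: validity, determinism, oracle agreement, constraints."""

import random

import pytest

from ffremap import (
    ConstraintError,
    NamingConstraints,
    NotIsomorphicError,
    brute_force_isomorphism,
    build_graph,
    find_isomorphism,
    invert_mapping,
    load_naming_csv,
    validate_mapping,
)
from ffremap.matcher import AtomMapping
from ffremap.molgraph import MolecularGraph
from ffremap.fixtures import make_molecule, make_variant

ELEMENTS = ("C", "H", "O", "N")


def random_connected_graph(rng: random.Random, n: int) -> MolecularGraph:
    """Random connected element-labeled graph: spanning tree + extra edges."""
    elements = tuple(rng.choice(ELEMENTS) for _ in range(n))
    names = tuple(f"{e}{i + 1}" for i, e in enumerate(elements))
    edges = {(rng.randint(1, v - 1), v) for v in range(2, n + 1)}
    extra = rng.randint(0, max(0, n - 2))
    for _ in range(extra):
        i, j = rng.sample(range(1, n + 1), 2)
        edges.add((min(i, j), max(i, j)))
    return MolecularGraph(n, elements, names, frozenset(edges))


def permute_graph(rng: random.Random, g: MolecularGraph):
    perm = list(range(1, g.n + 1))
    rng.shuffle(perm)
    elements = [None] * g.n
    names = [None] * g.n
    for i in range(1, g.n + 1):
        elements[perm[i - 1] - 1] = g.elements[i - 1]
        names[perm[i - 1] - 1] = g.names[i - 1]
    edges = frozenset(
        (min(perm[i - 1], perm[j - 1]), max(perm[i - 1], perm[j - 1]))
        for i, j in g.edges
    )
    return MolecularGraph(g.n, tuple(elements), tuple(names), edges), perm


def test_water_self_isomorphism_is_valid(water_top):
    g = build_graph(water_top)
    m = find_isomorphism(g, g)
    validate_mapping(m, g, g)
    assert m.apply(1) == 1  # the unique oxygen must map to itself


def test_water_vs_methane_not_isomorphic(water_top):
    g1 = build_graph(water_top)
    g2 = build_graph(make_molecule("alkane:1", name="CH4"))
    with pytest.raises(NotIsomorphicError, match="not isomorphic"):
        find_isomorphism(g1, g2)


def test_same_size_same_elements_different_wiring_not_isomorphic():
    # n-butane vs isobutane: same element multiset, different degree pattern
    g1 = build_graph(make_molecule("alkane:4"))
    atoms = make_molecule("alkane:4").atoms
    from ffremap import Bond, MoleculeTopology
    iso = MoleculeTopology("ISO", atoms, bonds=[
        Bond(1, 2), Bond(2, 3), Bond(2, 4),
        Bond(1, 5), Bond(1, 6), Bond(1, 7),
        Bond(3, 8), Bond(3, 9), Bond(3, 10),
        Bond(4, 11), Bond(4, 12), Bond(4, 13), Bond(2, 14),
    ])
    g2 = build_graph(iso)
    with pytest.raises(NotIsomorphicError):
        find_isomorphism(g1, g2)


def test_benzene_permutation_recovered_up_to_automorphism(benzene_top):
    g1 = build_graph(benzene_top)
    variant, perm = make_variant(benzene_top, seed=5)
    g2 = build_graph(variant)
    m = find_isomorphism(g1, g2)
    validate_mapping(m, g1, g2)
    # m composed with the inverse ground-truth permutation is an automorphism
    d = m.as_dict()
    inv_perm = {perm[i - 1]: i for i in range(1, g1.n + 1)}
    auto = {i: inv_perm[d[i]] for i in d}
    image = {(min(auto[i], auto[j]), max(auto[i], auto[j])) for i, j in g1.edges}
    assert image == set(g1.edges)
    assert all(g1.element(i) == g1.element(auto[i]) for i in auto)


def test_matcher_is_deterministic(paa_top):
    g1 = build_graph(paa_top)
    variant, _ = make_variant(paa_top, seed=17)
    g2 = build_graph(variant)
    results = {find_isomorphism(g1, g2).pairs for _ in range(5)}
    assert len(results) == 1


@pytest.mark.parametrize("trial", range(10))
def test_matcher_agrees_with_oracles_on_random_pairs(trial):
    """Existence agreement with the brute-force oracle and with networkx
    on random connected labeled graphs of up to 10 nodes."""
    nx = pytest.importorskip("networkx")
    from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

    rng = random.Random(1000 + trial)
    for _ in range(10):
        n = rng.randint(2, 10)
        g1 = random_connected_graph(rng, n)
        if rng.random() < 0.5:
            g2, _ = permute_graph(rng, g1)
        else:
            g2 = random_connected_graph(rng, n)
        oracle = brute_force_isomorphism(g1, g2)
        try:
            m = find_isomorphism(g1, g2)
            found = True
            validate_mapping(m, g1, g2)
        except NotIsomorphicError:
            found = False
        assert found == (oracle is not None)

        def to_nx(g):
            G = nx.Graph()
            for i in range(1, g.n + 1):
                G.add_node(i, element=g.element(i))
            G.add_edges_from(g.edges)
            return G

        nx_iso = GraphMatcher(
            to_nx(g1), to_nx(g2), node_match=categorical_node_match("element", None)
        ).is_isomorphic()
        assert found == nx_iso


def test_invert_mapping_swaps_and_resorts():
    m = AtomMapping.from_dict("X", {1: 2, 2: 3, 3: 1})
    assert invert_mapping(m).pairs == ((1, 3), (2, 1), (3, 2))
    assert invert_mapping(invert_mapping(m)) == m


def test_identity_mapping_inverts_to_itself():
    m = AtomMapping.from_dict("X", {i: i for i in range(1, 6)})
    assert invert_mapping(m) == m


# --- consistent-naming constraints ----------------------------------------


def _water_pair():
    top = make_molecule("water", name="SOL")
    variant, perm = make_variant(top, seed=8)
    return build_graph(top), build_graph(variant), perm


def test_fully_pinning_csv_returns_the_unique_consistent_mapping(tmp_path):
    g1, g2, perm = _water_pair()
    rows = ["current,new"]
    for i in range(1, 4):
        rows.append(f"{g1.names[i - 1]},{g2.names[perm[i - 1] - 1]}")
    csv_path = tmp_path / "names.csv"
    csv_path.write_text("\n".join(rows) + "\n")
    constraints = load_naming_csv(csv_path)
    m = find_isomorphism(g1, g2, constraints)
    assert m.as_dict() == {i: perm[i - 1] for i in range(1, 4)}


def test_contradictory_pin_raises_before_search():
    g1, g2, perm = _water_pair()
    # pin the oxygen name to a hydrogen name: different elements
    o_name = g1.names[0]
    h_name = next(n for i, n in enumerate(g2.names, 1) if g2.element(i) == "H")
    constraints = NamingConstraints(pairs=((o_name, h_name),))
    with pytest.raises(ConstraintError, match="different elements"):
        find_isomorphism(g1, g2, constraints)


def test_unsatisfiable_but_element_consistent_pins_report_not_isomorphic():
    g1, g2, perm = _water_pair()
    # pin both source hydrogens crosswise to the same target hydrogen names
    h1, h2 = (n for i, n in enumerate(g1.names, 1) if g1.element(i) == "H")
    t_h = [n for i, n in enumerate(g2.names, 1) if g2.element(i) == "H"]
    good = {g1.names[i - 1]: g2.names[perm[i - 1] - 1] for i in range(1, 4)}
    # swap the two hydrogen targets: still element-consistent, still satisfiable
    constraints = NamingConstraints(pairs=(
        (h1, good[h2]), (h2, good[h1]),
    ))
    m = find_isomorphism(g1, g2, constraints)
    validate_mapping(m, g1, g2)
    assert m.as_dict()[int(1)] == perm[0]  # oxygen still forced by element


def test_missing_constrained_name_is_an_error():
    g1, g2, _ = _water_pair()
    constraints = NamingConstraints(pairs=(("NOPE", g2.names[0]),))
    with pytest.raises(ConstraintError, match="NOPE"):
        find_isomorphism(g1, g2, constraints)


def test_duplicate_column_names_rejected():
    with pytest.raises(ConstraintError, match="unique"):
        NamingConstraints(pairs=(("A", "B"), ("A", "C")))


def test_headerless_csv_detected(tmp_path):
    g1, g2, perm = _water_pair()
    rows = [f"{g1.names[i - 1]},{g2.names[perm[i - 1] - 1]}" for i in range(1, 4)]
    p = tmp_path / "noheader.csv"
    p.write_text("\n".join(rows) + "\n")
    constraints = load_naming_csv(p)
    with pytest.raises(ConstraintError, match="header"):
        find_isomorphism(g1, g2, constraints)


def test_wall_limit_aborts_with_protonation_guidance(paa_top):
    from ffremap import MatchTimeout

    g1 = build_graph(paa_top)
    variant, _ = make_variant(paa_top, seed=2)
    g2 = build_graph(variant)
    with pytest.raises(MatchTimeout, match="protonation"):
        find_isomorphism(g1, g2, wall_limit=0.0)
    # and no limit by default: the same pair maps fine
    validate_mapping(find_isomorphism(g1, g2), g1, g2)


def test_brute_force_refuses_large_graphs():
    g = build_graph(make_molecule("phenylacetic-acid"))
    with pytest.raises(ValueError, match="limited"):
        brute_force_isomorphism(g, g)
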