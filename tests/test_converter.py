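"""System segmentation, conversion, back-conversion and restraint remapping."""

import pytest

from ffremap import (
    CompositionError,
    PosResRecord,
    SystemComposition,
    back_convert,
    build_graph,
    convert_system,
    find_isomorphism,
    remap_restraints,
    segment_system,
)
from ffremap.matcher import AtomMapping, MappingError
from ffremap.fixtures import make_molecule, make_system, make_variant


def test_segment_sizes_follow_composition(mixed_system):
    cf, comp, tops = mixed_system
    slices = segment_system(cf, comp, tops)
    assert [(n, b - a) for n, a, b in slices] == [
        ("SOL", 3), ("SOL", 3), ("K", 1), ("BZAA", 18)
    ]


def test_wrong_composition_reports_expected_vs_found(mixed_system):
    cf, _, tops = mixed_system
    bad = SystemComposition.from_lists(["SOL"], [3])
    with pytest.raises(CompositionError, match="9 atoms.*25"):
        segment_system(cf, bad, tops)


def test_single_water_permutation_hand_example():
    """Mapping {1->3, 2->1, 3->2}: source (O,H,H) coordinates land at output
    positions (3,1,2) under the target's names (H1,H2,OW)."""
    src = make_molecule("water", name="SOL")
    tgt = make_molecule("water", name="SOL")
    tgt.atoms = [
        tgt.atoms[1]._replace(index=1, atom_name="H1"),
        tgt.atoms[2]._replace(index=2, atom_name="H2"),
        tgt.atoms[0]._replace(index=3, atom_name="OW"),
    ]
    tgt.settles = tgt.settles._replace(ow=3)
    comp = SystemComposition.from_lists(["SOL"], [1])
    cf = make_system(comp, {"SOL": src}, seed=4)
    m = AtomMapping.from_dict("SOL", {1: 3, 2: 1, 3: 2})
    out = convert_system(cf, comp, {"SOL": m}, {"SOL": tgt})
    o, h1, h2 = cf.atoms
    assert [(a.x, a.y, a.z) for a in out.atoms] == [
        (h1.x, h1.y, h1.z), (h2.x, h2.y, h2.z), (o.x, o.y, o.z)
    ]
    assert [a.atom_name for a in out.atoms] == ["H1", "H2", "OW"]


def test_conversion_conserves_coordinates_box_and_velocities(converted_setup):
    cf, comp, tops, variants, perms, mappings = converted_setup
    out = convert_system(cf, comp, mappings, variants)
    assert out.n_atoms == cf.n_atoms
    assert out.box == cf.box
    assert sorted((a.x, a.y, a.z) for a in out.atoms) == sorted(
        (a.x, a.y, a.z) for a in cf.atoms
    )


def test_round_trip_restores_records_exactly(converted_setup):
    cf, comp, tops, variants, perms, mappings = converted_setup
    out = convert_system(cf, comp, mappings, variants)
    back = back_convert(out, comp, mappings, tops)
    assert back.atoms == cf.atoms
    assert back.box == cf.box


def test_round_trip_with_velocities(converted_setup):
    _, comp, tops, variants, _, mappings = converted_setup
    cf = make_system(comp, tops, seed=21, velocities=True)
    out = convert_system(cf, comp, mappings, variants)
    assert out.has_velocities
    back = back_convert(out, comp, mappings, tops)
    assert back.atoms == cf.atoms


def test_output_numbering_is_sequential_and_residues_non_decreasing(converted_setup):
    cf, comp, tops, variants, _, mappings = converted_setup
    out = convert_system(cf, comp, mappings, variants)
    assert [a.atom_number for a in out.atoms] == list(range(1, cf.n_atoms + 1))
    res = [a.res_number for a in out.atoms]
    assert all(b - a in (0, 1) for a, b in zip(res, res[1:]))
    # 2 waters + 1 ion + 1 single-residue ligand = 4 residues
    assert res[0] == 1 and res[-1] == 4


def test_multi_residue_molecule_renumbered_from_target_topology():
    top = make_molecule("protein:60", seed=6, name="PR")
    variant, _ = make_variant(top, seed=7)
    m = find_isomorphism(build_graph(top), build_graph(variant), mol_name="PR")
    comp = SystemComposition.from_lists(["PR"], [2])
    cf = make_system(comp, {"PR": top}, seed=8)
    out = convert_system(cf, comp, {"PR": m}, {"PR": variant})
    n_res_target = variant.atoms[-1].res_index
    res = [a.res_number for a in out.atoms]
    assert res[-1] == 2 * n_res_target
    back = back_convert(out, comp, {"PR": m}, {"PR": top})
    assert back.atoms == cf.atoms


def test_changing_one_molecule_only_changes_its_records(converted_setup):
    cf, comp, tops, variants, _, mappings = converted_setup
    out1 = convert_system(cf, comp, mappings, variants)
    # shift the ion (atom index 6, 0-based slice [6:7]) by 0.1 nm
    import dataclasses
    moved = dataclasses.replace(cf, atoms=list(cf.atoms))
    moved.atoms[6] = moved.atoms[6]._replace(x=round(moved.atoms[6].x + 0.1, 3))
    out2 = convert_system(moved, comp, mappings, variants)
    diffs = [k for k, (a, b) in enumerate(zip(out1.atoms, out2.atoms)) if a != b]
    assert diffs == [6]


def test_missing_mapping_is_a_lookup_error(mixed_system):
    cf, comp, tops = mixed_system
    with pytest.raises(MappingError, match="SOL"):
        convert_system(cf, comp, {}, tops)


def test_remap_restraints_moves_indices_and_keeps_forces():
    m = AtomMapping.from_dict("X", {1: 5, 2: 3, 3: 1, 4: 2, 5: 4})
    recs = [PosResRecord(1, 1, (1000.0, 1000.0, 1000.0)),
            PosResRecord(3, 1, (500.0, 500.0, 500.0))]
    out = remap_restraints(recs, m)
    assert [(r.index, r.forces[0]) for r in out] == [(1, 500.0), (5, 1000.0)]


def test_remap_restraints_set_image_under_random_permutation(paa_top):
    variant, perm = make_variant(paa_top, seed=13)
    m = AtomMapping.from_dict("BZAA", {i: perm[i - 1] for i in range(1, 19)})
    heavy = [a.index for a in paa_top.atoms if a.mass > 2.0]
    recs = [PosResRecord(i, 1, (1000.0,) * 3) for i in heavy]
    out = remap_restraints(recs, m)
    assert {r.index for r in out} == {perm[i - 1] for i in heavy}
    ident = AtomMapping.from_dict("BZAA", {i: i for i in range(1, 19)})
    assert remap_restraints(recs, ident) == sorted(recs, key=lambda r: r.index)


def test_restraint_index_outside_mapping_rejected():
    m = AtomMapping.from_dict("X", {1: 1})
    with pytest.raises(MappingError, match="outside"):
        remap_restraints([PosResRecord(7, 1, (1.0,))], m)
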