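import pytest

from ffremap import SystemComposition, build_graph
from ffremap.fixtures import make_molecule, make_system, make_variant


@pytest.fixture
def water_top():
    return make_molecule("water", name="SOL")


@pytest.fixture
def paa_top():
    return make_molecule("phenylacetic-acid", name="BZAA")


@pytest.fixture
def benzene_top():
    return make_molecule("benzene", name="BNZ")


@pytest.fixture
def mixed_system():
    """Small heterogeneous system: 2 waters, 1 K+ ion, 1 phenylacetic acid."""
    tops = {
        "SOL": make_molecule("water", name="SOL"),
        "K": make_molecule("ion:K", name="K"),
        "BZAA": make_molecule("phenylacetic-acid", name="BZAA"),
    }
    comp = SystemComposition.from_lists(["SOL", "K", "BZAA"], [2, 1, 1])
    cf = make_system(comp, tops, seed=9)
    return cf, comp, tops


@pytest.fixture
def converted_setup(mixed_system):
    """Mixed system plus permuted variants, graphs and mappings per species."""
    from ffremap import find_isomorphism

    cf, comp, tops = mixed_system
    variants, perms, mappings = {}, {}, {}
    for i, (name, top) in enumerate(tops.items()):
        var, perm = make_variant(top, seed=100 + i)
        variants[name] = var
        perms[name] = perm
        mappings[name] = find_isomorphism(
            build_graph(top), build_graph(var), mol_name=name
        )
    return cf, comp, tops, variants, perms, mappings
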