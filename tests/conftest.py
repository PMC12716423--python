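import dendropy
import numpy as np
import pytest

from alpassembly.classe import ClasseParameters, build_generators
from alpassembly.state_space import Biome, RegionSet, build_state_space


@pytest.fixture(scope="session")
def one_region_space():
    return build_state_space(RegionSet.complete(["X"]), 1)


@pytest.fixture(scope="session")
def two_region_space():
    return build_state_space(
        RegionSet.from_pairs(["X", "Y"], [("X", "Y")]), 2)


@pytest.fixture(scope="session")
def chain3_space():
    """Three regions in a chain X - Y - Z, ranges up to two regions."""
    return build_state_space(
        RegionSet.from_pairs(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")]), 2)


@pytest.fixture(scope="session")
def chain3_full():
    return build_state_space(
        RegionSet.from_pairs(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")]), 3)


@pytest.fixture()
def pure_birth(one_region_space):
    """One-region pure-birth setup: lambda = 1, no extinction, rho = 1."""
    params = ClasseParameters(lambda_within=1.0, lambda_between=0.0,
                              dispersal=0.0, biome_rate=0.0, extirpation=0.0)
    gen = build_generators(params, one_region_space)
    tree = dendropy.Tree.get(data="(a:1,b:1);", schema="newick")
    iA = one_region_space.index_of(
        one_region_space.state(["X"], Biome.ALPINE))
    tips = {"a": {iA}, "b": {iA}}
    return gen, tree, tips, iA


@pytest.fixture()
def two_region_model(two_region_space):
    sp = two_region_space
    params = ClasseParameters(lambda_within=0.3, lambda_between=0.1,
                              dispersal=0.15, biome_rate=0.2,
                              extirpation=0.05)
    gen = build_generators(params, sp)
    tree = dendropy.Tree.get(data="((a:1,b:1):1,c:2);", schema="newick")
    tips = {
        "a": {sp.index_of(sp.state(["X"], Biome.ALPINE))},
        "b": {sp.index_of(sp.state(["Y"], Biome.NONALPINE))},
        "c": {sp.index_of(sp.state(["X", "Y"], Biome.BOTH))},
    }
    return gen, tree, tips
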