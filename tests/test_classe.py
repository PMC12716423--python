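"""Generator assembly, likelihood behavior and the forward simulator."""

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from alpassembly.classe import (
    ClasseParameters,
    TreeIndex,
    build_generators,
    classe_loglik,
    read_tip_data,
    simulate_clade,
    write_tip_data,
)
from alpassembly.state_space import Biome, CladoClass


def test_parameter_validation():
    with pytest.raises(ValueError):
        ClasseParameters(-0.1, 0, 0, 0, 0)
    with pytest.raises(ValueError):
        ClasseParameters(0.1, 0, 0, 0, 0, sampling_fraction=0.0)


def test_generator_rates(chain3_space):
    sp = chain3_space
    p = ClasseParameters(lambda_within=0.3, lambda_between=0.2,
                         dispersal=0.07, biome_rate=0.11, extirpation=0.05)
    gen = build_generators(p, sp)
    # single-region single-biome: total cladogenetic rate = lambda_within
    i = sp.index_of(sp.state(["X"], Biome.ALPINE))
    assert gen.lambda_tot[i] == pytest.approx(0.3)
    # no direct nonalpine -> alpine; shift to BOTH at biome_rate
    ia = sp.index_of(sp.state(["X"], Biome.NONALPINE))
    iA = sp.index_of(sp.state(["X"], Biome.ALPINE))
    iB = sp.index_of(sp.state(["X"], Biome.BOTH))
    assert gen.Q[ia, iA] == 0.0
    assert gen.Q[ia, iB] == pytest.approx(0.11)
    # one valid bipartition of {X,Y} gets the whole between-region rate
    ixy = sp.index_of(sp.state(["X", "Y"], Biome.ALPINE))
    between = [o for o in range(len(gen.out_rate))
               if gen.out_parent[o] == ixy
               and gen.out_class[o] == CladoClass.BETWEEN_REGION]
    assert len(between) == 1
    assert gen.out_rate[between[0]] == pytest.approx(0.2)
    # mixed-biome parent splits lambda_within over its three outcomes
    ib = sp.index_of(sp.state(["X"], Biome.BOTH))
    rates = gen.out_rate[gen.out_parent == ib]
    assert rates == pytest.approx([0.1, 0.1, 0.1])
    # dispersal scales with the number of occupied adjacent regions
    iy = sp.index_of(sp.state(["Y"], Biome.ALPINE))
    assert gen.Q[iy, ixy] == pytest.approx(0.07)
    # extirpation only kills single-region lineages
    assert gen.mu[ixy] == 0.0 and gen.mu[iy] == pytest.approx(0.05)


def test_pure_birth_closed_form(pure_birth):
    """Two tips, unit branches, lambda=1, mu=0, rho=1: logL = -2 + log 1."""
    gen, tree, tips, _ = pure_birth
    ll = classe_loglik(tree, tips, gen, 1.0, condition_on_survival=False,
                       rtol=1e-11, atol=1e-13)
    assert ll == pytest.approx(-2.0, abs=1e-8)


def test_no_extinction_complete_sampling_gives_zero_E(pure_birth):
    from alpassembly.classe import _Rates, _solve_E
    gen, *_ = pure_birth
    sol = _solve_E(_Rates(gen), 1.0, 5.0, 1e-10, 1e-12)
    for t in np.linspace(0, 5, 20):
        assert np.allclose(sol.sol(t), 0.0, atol=1e-12)


def test_likelihood_invariant_to_child_swap(two_region_model):
    gen, _, tips = two_region_model
    t1 = dendropy.Tree.get(data="((a:1,b:1):1,c:2);", schema="newick")
    t2 = dendropy.Tree.get(data="(c:2,(b:1,a:1):1);", schema="newick")
    ll1 = classe_loglik(t1, tips, gen)
    ll2 = classe_loglik(t2, tips, gen)
    assert ll1 == pytest.approx(ll2, rel=1e-9)


def test_grid_method_matches_ode(two_region_model):
    gen, tree, tips = two_region_model
    ll = classe_loglik(tree, tips, gen)
    llg = classe_loglik(tree, tips, gen, method="grid", n_grid=400)
    assert llg == pytest.approx(ll, abs=2e-3)


def test_root_weighting_options(two_region_model):
    gen, tree, tips = two_region_model
    ll_fj = classe_loglik(tree, tips, gen, root_weighting="fitzjohn")
    ll_u = classe_loglik(tree, tips, gen, root_weighting="uniform")
    assert ll_fj > ll_u  # likelihood-proportional weights dominate uniform


def test_tree_index_rejects_bad_trees():
    with pytest.raises(ValueError):
        TreeIndex(dendropy.Tree.get(data="(a:1,b:2);", schema="newick"))
    with pytest.raises(ValueError):
        TreeIndex(dendropy.Tree.get(data="(a:1,b:1,c:1);", schema="newick"))


def test_simulator_zero_rates_is_inert(one_region_space):
    p = ClasseParameters(0.0, 0.0, 0.0, 0.0, 0.0)
    gen = build_generators(p, one_region_space)
    iA = one_region_space.index_of(
        one_region_space.state(["X"], Biome.ALPINE))
    tree, truth, tips = simulate_clade(gen, iA, 5.0, seed=1, min_tips=1)
    assert len(truth.branches) == 1
    assert truth.branches[0].events == []
    assert truth.branches[0].start_state == truth.branches[0].end_state == iA


def test_simulator_closure_without_dispersal(chain3_space):
    p = ClasseParameters(0.4, 0.1, 0.0, 0.2, 0.05)
    gen = build_generators(p, chain3_space)
    iA = chain3_space.index_of(chain3_space.state(["X"], Biome.ALPINE))
    tree, truth, tips = simulate_clade(gen, iA, 8.0, seed=3, min_tips=1)
    for b in truth.branches:
        states = {b.start_state, b.end_state}
        states |= {s for ev in b.events for s in (ev.from_state,
                                                  *ev.to_states)}
        assert all(chain3_space[s].range_size == 1 for s in states)


def test_simulator_yule_mean_tips(pure_birth):
    """Yule process: E[tips at t] = e^(lambda t)."""
    gen, *_ , iA = pure_birth
    counts = []
    for s in range(1000):
        _, truth, _ = simulate_clade(gen, iA, 3.0, seed=s, min_tips=1)
        counts.append(truth.extra["n_extant"])
    mean = np.mean(counts)
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(mean - np.exp(3.0)) < 3 * se


def test_simulator_reproducible(chain3_space):
    p = ClasseParameters(0.3, 0.05, 0.1, 0.1, 0.05)
    gen = build_generators(p, chain3_space)
    iA = chain3_space.index_of(chain3_space.state(["Y"], Biome.ALPINE))
    r1 = simulate_clade(gen, iA, 10.0, seed=7)
    r2 = simulate_clade(gen, iA, 10.0, seed=7)
    assert r1[1] == r2[1]
    assert r1[0].as_string(schema="newick") == r2[0].as_string(schema="newick")


def test_q_only_occupancy_matches_matrix_exponential(one_region_space):
    """With lambda = mu = 0 the simulator is a plain CTMC; end-state
    frequencies must match the matrix-exponential transition kernel."""
    sp = one_region_space
    p = ClasseParameters(0.0, 0.0, 0.0, 0.35, 0.0)
    gen = build_generators(p, sp)
    ia = sp.index_of(sp.state(["X"], Biome.NONALPINE))
    T = 3.0
    counts = np.zeros(sp.n_states)
    n_rep = 1500
    for s in range(n_rep):
        _, truth, _ = simulate_clade(gen, ia, T, seed=s, min_tips=1)
        counts[truth.branches[0].end_state] += 1
    freq = counts / n_rep
    G = gen.Q - np.diag(gen.q_tot)
    target = expm(G * T)[ia]
    assert np.all(np.abs(freq - target)
                  <= 3 * np.sqrt(target * (1 - target) / n_rep) + 5 / n_rep)


def test_tip_data_tsv_roundtrip(tmp_path, chain3_space):
    sp = chain3_space
    tips = {
        "t1": {sp.index_of(sp.state(["X"], Biome.ALPINE))},
        "t2": {sp.index_of(sp.state(["X", "Y"], Biome.BOTH))},
        "t3": set(range(sp.n_states)),
    }
    path = tmp_path / "tips.tsv"
    write_tip_data(tips, sp, path)
    assert read_tip_data(path, sp) == tips
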