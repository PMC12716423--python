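"""JSON history format round-trips, validation, event classification."""

from collections import Counter

import pytest

from alpassembly.classe import ClasseParameters, build_generators, simulate_clade
from alpassembly.history import (
    AssemblyEvent,
    BranchHistory,
    Event,
    EventKind,
    HistoryValidationError,
    MappedHistory,
    Process,
    classify_events,
    read_histories,
    validate_history,
    write_histories,
)
from alpassembly.state_space import Biome


def two_branch_history(sp):
    """Hand-built history: root splits; one daughter shifts biome."""
    iA = sp.index_of(sp.state(["X"], Biome.ALPINE))
    iB = sp.index_of(sp.state(["X"], Biome.BOTH))
    root_ev = Event(age=2.0, kind=EventKind.CLADOGENETIC_NODE,
                    move_class="WITHIN_REGION", from_state=iA,
                    to_states=(iA, iA), state_changed=False)
    shift = Event(age=1.2, kind=EventKind.ANAGENETIC,
                  move_class="BIOME_SHIFT", from_state=iA, to_states=(iB,),
                  state_changed=True, extra={"note": "kept"})
    return MappedHistory(branches=[
        BranchHistory(0, -1, 0, 2.0, 2.0, iA, iA, [root_ev]),
        BranchHistory(1, 0, 1, 2.0, 0.0, iA, iB, [shift], label="a"),
        BranchHistory(2, 0, 2, 2.0, 0.0, iA, iA, [], label="b"),
    ], extra={"replicate": 3})


def test_roundtrip_identity(tmp_path, one_region_space):
    h = two_branch_history(one_region_space)
    path = tmp_path / "h.json"
    write_histories([h], path)
    assert read_histories(path) == [h]


def test_empty_events_roundtrip(tmp_path, one_region_space):
    sp = one_region_space
    iA = sp.index_of(sp.state(["X"], Biome.ALPINE))
    h = MappedHistory(branches=[BranchHistory(0, -1, 0, 1.0, 0.0, iA, iA)])
    path = tmp_path / "h.json"
    write_histories([h], path)
    assert read_histories(path) == [h]


def test_unknown_fields_are_preserved(tmp_path, one_region_space):
    h = two_branch_history(one_region_space)
    path = tmp_path / "h.json"
    write_histories([h], path)
    back = read_histories(path)[0]
    assert back.extra["replicate"] == 3
    assert back.branches[1].events[0].extra["note"] == "kept"


def test_broken_chain_names_the_branch(one_region_space):
    h = two_branch_history(one_region_space)
    h.branches[1].events[0].from_state = 99
    with pytest.raises(HistoryValidationError, match="branch 1"):
        validate_history(h)


def test_inconsistent_flag_and_end_state_rejected(one_region_space):
    h = two_branch_history(one_region_space)
    h.branches[1].events[0].state_changed = False
    with pytest.raises(HistoryValidationError, match="state_changed"):
        validate_history(h)
    h = two_branch_history(one_region_space)
    h.branches[1].end_state = h.branches[1].start_state
    with pytest.raises(HistoryValidationError, match="end_state"):
        validate_history(h)


@pytest.mark.parametrize("parent,daughters,expect", [
    # in situ: endemic alpine parent, counted once per event
    ((("X",), Biome.ALPINE), [(("X",), Biome.ALPINE), (("X",), Biome.ALPINE)],
     [(Process.IN_SITU_SPECIATION, 0)]),
    # biome-subset: mixed-biome parent buds an alpine endemic
    ((("X",), Biome.BOTH), [(("X",), Biome.BOTH), (("X",), Biome.ALPINE)],
     [(Process.SUBSET_SPECIATION, 0)]),
    # range-subset via vicariance: both daughters are new endemics
    ((("X", "Y"), Biome.ALPINE),
     [(("X",), Biome.ALPINE), (("Y",), Biome.ALPINE)],
     [(Process.SUBSET_SPECIATION, 0), (Process.SUBSET_SPECIATION, 1)]),
], ids=["in-situ", "biome-subset", "vicariant-subset"])
def test_cladogenetic_classification(chain3_space, parent, daughters, expect):
    sp = chain3_space
    pi = sp.index_of(sp.state(*parent))
    ds = tuple(sp.index_of(sp.state(*d)) for d in daughters)
    ev = Event(age=1.0, kind=EventKind.CLADOGENETIC_NODE,
               move_class="WITHIN_REGION", from_state=pi, to_states=ds,
               state_changed=any(d != pi for d in ds))
    h = MappedHistory(branches=[
        BranchHistory(0, -1, 0, 1.0, 1.0, pi, pi, [ev])])
    got = [(e.process, e.region) for e in classify_events(h, sp)]
    assert sorted(got) == sorted(expect)


def test_colonization_sources_and_weights(chain3_space):
    sp = chain3_space
    frm = sp.index_of(sp.state(["X", "Y"], Biome.ALPINE))
    # expansion is recorded from the state before the move
    frm_one = sp.index_of(sp.state(["X"], Biome.ALPINE))
    to_xy = sp.index_of(sp.state(["X", "Y"], Biome.ALPINE))
    ev = Event(age=3.0, kind=EventKind.ANAGENETIC,
               move_class="RANGE_EXPANSION", from_state=frm_one,
               to_states=(to_xy,), state_changed=True)
    h = MappedHistory(branches=[
        BranchHistory(0, -1, 0, 4.0, 0.0, frm_one, to_xy, [ev])])
    out = classify_events(h, sp)
    assert len(out) == 1
    e = out[0]
    assert e.process == Process.COLONIZATION and e.region == 1
    assert e.source_regions == ((0, 1.0),)


def test_niche_shift_counted_per_region(chain3_space):
    sp = chain3_space
    frm = sp.index_of(sp.state(["X", "Y"], Biome.NONALPINE))
    to = sp.index_of(sp.state(["X", "Y"], Biome.BOTH))
    ev = Event(age=2.0, kind=EventKind.ANAGENETIC, move_class="BIOME_SHIFT",
               from_state=frm, to_states=(to,), state_changed=True)
    h = MappedHistory(branches=[
        BranchHistory(0, -1, 0, 3.0, 0.0, frm, to, [ev])])
    out = classify_events(h, sp)
    assert Counter(e.process for e in out) == {Process.NICHE_EXPANSION: 2}
    assert {e.region for e in out} == {0, 1}


def test_hidden_events_classified_like_nodes(chain3_space):
    sp = chain3_space
    pi = sp.index_of(sp.state(["X"], Biome.ALPINE))
    ev = Event(age=1.5, kind=EventKind.CLADOGENETIC_HIDDEN,
               move_class="WITHIN_REGION", from_state=pi, to_states=(pi,),
               state_changed=False)
    h = MappedHistory(branches=[
        BranchHistory(0, -1, 0, 2.0, 0.0, pi, pi, [ev])])
    assert [(e.process, e.region) for e in classify_events(h, sp)] == [
        (Process.IN_SITU_SPECIATION, 0)]
    assert classify_events(h, sp, include_hidden=False) == []


def test_classification_invariant_under_branch_reordering(chain3_space):
    p = ClasseParameters((0.4, 0.2, 0.1), 0.05, 0.1, 0.1, 0.04)
    gen = build_generators(p, chain3_space)
    iA = chain3_space.index_of(chain3_space.state(["X"], Biome.ALPINE))
    _, truth, _ = simulate_clade(gen, iA, 10.0, seed=2)
    base = Counter((e.process, e.region)
                   for e in classify_events(truth, chain3_space))
    shuffled = MappedHistory(branches=list(reversed(truth.branches)),
                             extra=truth.extra)
    again = Counter((e.process, e.region)
                    for e in classify_events(shuffled, chain3_space))
    assert base == again


@pytest.mark.parametrize("preset,seed", [
    ("SPECIATION_ENGINE", 5), ("RECRUITMENT", 5), ("CROSSROADS", 5),
    ("SPECIATION_ENGINE", 11), ("CROSSROADS", 23),
])
def test_classifier_matches_simulator_tally(preset, seed):
    """Two independent accountings of the same history must agree exactly."""
    from alpassembly.synthetic import CladeScenario, make_scenario_clade
    sc = make_scenario_clade(CladeScenario(preset=preset, seed=seed))
    validate_history(sc.truth)
    got = Counter(f"{e.process}:{e.region}"
                  for e in classify_events(sc.truth, sc.space))
    assert got == Counter(sc.truth.extra["simulator_tally"])


def test_assembly_event_weight_validation():
    with pytest.raises(ValueError):
        AssemblyEvent(1.0, 0, Process.COLONIZATION,
                      source_regions=((1, 0.4),))
    with pytest.raises(ValueError):
        AssemblyEvent(1.0, 0, "NOT_A_PROCESS")
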