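"""Serialization and biological classification of mapped histories.

A *mapped history* is one replicate joint reconstruction of range and
biome evolution on a phylogeny: for every branch, the state at both ends
plus a typed, timed list of events (anagenetic moves, cladogenetic events
at observed nodes, and hidden cladogenetic events whose sibling left no
sampled descendants).  Histories are stored in a versioned JSON format;
unknown fields round-trip untouched so the format stays extensible.

``classify_events`` turns raw state changes into the assembly-process
vocabulary used throughout the package: in situ speciation, subset
speciation, colonization, niche expansion/contraction and local
extinction, each localized to a region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .state_space import AnaClass, Biome, CompoundState, StateSpace

__all__ = [
    "EventKind",
    "Process",
    "Event",
    "BranchHistory",
    "MappedHistory",
    "AssemblyEvent",
    "HistoryValidationError",
    "write_histories",
    "read_histories",
    "classify_events",
    "assembly_events_to_frame",
]

FORMAT_VERSION = "1.0"
_AGE_TOL = 1e-9


class EventKind:
    ANAGENETIC = "ANAGENETIC"
    CLADOGENETIC_NODE = "CLADOGENETIC_NODE"
    CLADOGENETIC_HIDDEN = "CLADOGENETIC_HIDDEN"


class Process:
    """Closed vocabulary of assembly processes."""

    IN_SITU_SPECIATION = "IN_SITU_SPECIATION"
    SUBSET_SPECIATION = "SUBSET_SPECIATION"
    COLONIZATION = "COLONIZATION"
    NICHE_EXPANSION = "NICHE_EXPANSION"
    NICHE_CONTRACTION = "NICHE_CONTRACTION"
    LOCAL_EXTINCTION = "LOCAL_EXTINCTION"

    ALL = (IN_SITU_SPECIATION, SUBSET_SPECIATION, COLONIZATION,
           NICHE_EXPANSION, NICHE_CONTRACTION, LOCAL_EXTINCTION)


@dataclass
class Event:
    """One evolutionary event on a branch.

    ``to_states`` holds one state index for anagenetic and hidden
    cladogenetic events and the ordered daughter pair for node events.
    """

    age: float
    kind: str
    move_class: str | None
    from_state: int
    to_states: tuple[int, ...]
    state_changed: bool
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "age": self.age,
            "kind": self.kind,
            "move_class": self.move_class,
            "from_state": self.from_state,
            "to_states": list(self.to_states),
            "state_changed": self.state_changed,
        }
        d.update(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        known = {"age", "kind", "move_class", "from_state", "to_states",
                 "state_changed"}
        return cls(
            age=float(d["age"]),
            kind=d["kind"],
            move_class=d.get("move_class"),
            from_state=int(d["from_state"]),
            to_states=tuple(int(s) for s in d["to_states"]),
            state_changed=bool(d["state_changed"]),
            extra={k: v for k, v in d.items() if k not in known},
        )


@dataclass
class BranchHistory:
    """Piecewise state history of one branch, ages in Ma (tip-ward = 0)."""

    branch_index: int
    parent_node: int
    child_node: int
    start_age: float   # rootward end (older)
    end_age: float     # tipward end (younger)
    start_state: int
    end_state: int
    events: list[Event] = field(default_factory=list)
    label: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "branch_index": self.branch_index,
            "parent_node": self.parent_node,
            "child_node": self.child_node,
            "start_age": self.start_age,
            "end_age": self.end_age,
            "start_state": self.start_state,
            "end_state": self.end_state,
            "events": [e.to_dict() for e in self.events],
        }
        if self.label is not None:
            d["label"] = self.label
        d.update(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BranchHistory":
        known = {"branch_index", "parent_node", "child_node", "start_age",
                 "end_age", "start_state", "end_state", "events", "label"}
        return cls(
            branch_index=int(d["branch_index"]),
            parent_node=int(d["parent_node"]),
            child_node=int(d["child_node"]),
            start_age=float(d["start_age"]),
            end_age=float(d["end_age"]),
            start_state=int(d["start_state"]),
            end_state=int(d["end_state"]),
            events=[Event.from_dict(e) for e in d["events"]],
            label=d.get("label"),
            extra={k: v for k, v in d.items() if k not in known},
        )


@dataclass
class MappedHistory:
    """One replicate joint biogeographic history over a whole tree."""

    branches: list[BranchHistory]
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"branches": [b.to_dict() for b in self.branches]}
        d.update(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MappedHistory":
        return cls(
            branches=[BranchHistory.from_dict(b) for b in d["branches"]],
            extra={k: v for k, v in d.items() if k != "branches"},
        )


class HistoryValidationError(ValueError):
    pass


def validate_history(history: MappedHistory) -> None:
    """Check age ordering and event/state chaining; raise with coordinates."""
    for b in history.branches:
        where = f"branch {b.branch_index}"
        if b.start_age < b.end_age - _AGE_TOL:
            raise HistoryValidationError(
                f"{where}: start_age {b.start_age} younger than end_age {b.end_age}")
        state = b.start_state
        prev_age = b.start_age
        for i, ev in enumerate(b.events):
            if ev.age > prev_age + _AGE_TOL or ev.age < b.end_age - _AGE_TOL:
                raise HistoryValidationError(
                    f"{where}, event {i}: age {ev.age} outside "
                    f"[{b.end_age}, {prev_age}]")
            if ev.from_state != state:
                raise HistoryValidationError(
                    f"{where}, event {i}: from_state {ev.from_state} breaks "
                    f"the chain (expected {state})")
            changed = any(t != ev.from_state for t in ev.to_states)
            if bool(ev.state_changed) != changed:
                raise HistoryValidationError(
                    f"{where}, event {i}: state_changed flag inconsistent")
            if ev.kind == EventKind.CLADOGENETIC_NODE:
                if i != len(b.events) - 1 or abs(ev.age - b.end_age) > 1e-6:
                    raise HistoryValidationError(
                        f"{where}, event {i}: node event not at branch end")
                # the lineage's own end state is unchanged by the node event
            else:
                if len(ev.to_states) != 1:
                    raise HistoryValidationError(
                        f"{where}, event {i}: {ev.kind} needs exactly one "
                        "target state")
                state = ev.to_states[0]
            prev_age = ev.age
        if state != b.end_state:
            raise HistoryValidationError(
                f"{where}: events end in state {state}, "
                f"branch end_state is {b.end_state}")


def write_histories(histories: Sequence[MappedHistory], path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "n_histories": len(histories),
        "histories": [h.to_dict() for h in histories],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_histories(path) -> list[MappedHistory]:
    with open(path) as fh:
        doc = json.load(fh)
    if "format_version" not in doc:
        raise HistoryValidationError("missing format_version")
    histories = [MappedHistory.from_dict(h) for h in doc["histories"]]
    for h in histories:
        validate_history(h)
    return histories


@dataclass
class AssemblyEvent:
    """A classified assembly-process event localized to one region."""

    age: float
    region: int
    process: str
    source_regions: tuple[tuple[int, float], ...] = ()
    detail: str | None = None
    branch_index: int | None = None

    def __post_init__(self):
        if self.process not in Process.ALL:
            raise ValueError(f"unknown process {self.process}")
        if self.source_regions:
            total = sum(w for _, w in self.source_regions)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("colonization source weights must sum to 1")


def _single_focal(state: CompoundState, focal: Biome) -> int | None:
    """Region index if ``state`` is a single-region pure-focal state."""
    if state.range_size == 1 and state.biome == focal:
        return state.regions[0]
    return None


def classify_events(
    history: MappedHistory,
    space: StateSpace,
    focal_biome: Biome = Biome.ALPINE,
    include_hidden: bool = True,
    source_attribution: str = "range",
) -> list[AssemblyEvent]:
    """Classify a mapped history into per-region assembly events.

    Definitions with respect to the focal biome (alpine by default):

    * IN_SITU_SPECIATION in r: a cladogenetic event whose parent is
      exactly ``({r}, focal)`` (the daughters are then forced to be the
      same state); counted once per event.
    * SUBSET_SPECIATION in r: a cladogenetic event producing a daughter
      ``({r}, focal)`` from a parent that strictly contains region r's
      focal biome (wider range and/or mixed biome).  ``detail`` records
      whether the parent exceeded the daughter in range, biome, or both.
    * COLONIZATION into r: anagenetic range expansion adding r while the
      biome includes the focal biome.  Sources are the regions occupied at
      event time with equal weights ("range" attribution) or only those
      adjacent to r ("adjacent" attribution).
    * NICHE_EXPANSION / NICHE_CONTRACTION in r: biome shift gaining /
      losing the focal biome, counted once per occupied region.
    * LOCAL_EXTINCTION in r: range contraction dropping r (or lineage
      death of a single-region endemic) while occupying the focal biome.
    """
    if source_attribution not in ("range", "adjacent"):
        raise ValueError("source_attribution must be 'range' or 'adjacent'")
    adj = space.regions.adjacency
    out: list[AssemblyEvent] = []

    def has_focal(b: Biome) -> bool:
        return b == focal_biome or b == Biome.BOTH

    def clado(ev: Event, b: BranchHistory, daughters: list[int]) -> None:
        parent = space[ev.from_state]
        r0 = _single_focal(parent, focal_biome)
        if r0 is not None:
            out.append(AssemblyEvent(ev.age, r0, Process.IN_SITU_SPECIATION,
                                     branch_index=b.branch_index))
            return
        if not has_focal(parent.biome):
            return
        for di in daughters:
            d = space[di]
            r = _single_focal(d, focal_biome)
            if r is None or not (parent.range_mask >> r & 1):
                continue
            wider = parent.range_size > 1
            mixed = parent.biome == Biome.BOTH
            detail = ("RANGE_AND_BIOME_SUBSET" if wider and mixed
                      else "RANGE_SUBSET" if wider else "BIOME_SUBSET")
            out.append(AssemblyEvent(ev.age, r, Process.SUBSET_SPECIATION,
                                     detail=detail, branch_index=b.branch_index))

    for b in history.branches:
        for ev in b.events:
            frm = space[ev.from_state]
            if ev.kind == EventKind.CLADOGENETIC_NODE:
                clado(ev, b, list(ev.to_states))
            elif ev.kind == EventKind.CLADOGENETIC_HIDDEN:
                if include_hidden:
                    clado(ev, b, list(ev.to_states))
            elif ev.kind == EventKind.ANAGENETIC:
                if ev.move_class == AnaClass.RANGE_EXPANSION:
                    to = space[ev.to_states[0]]
                    added = to.range_mask ^ frm.range_mask
                    r = added.bit_length() - 1
                    if has_focal(frm.biome):
                        if source_attribution == "range":
                            srcs = frm.regions
                        else:
                            srcs = tuple(i for i in frm.regions if adj[i, r])
                        w = 1.0 / len(srcs)
                        out.append(AssemblyEvent(
                            ev.age, r, Process.COLONIZATION,
                            source_regions=tuple((s, w) for s in srcs),
                            branch_index=b.branch_index))
                elif ev.move_class == AnaClass.RANGE_CONTRACTION:
                    to = space[ev.to_states[0]]
                    dropped = frm.range_mask ^ to.range_mask
                    r = dropped.bit_length() - 1
                    if has_focal(frm.biome):
                        out.append(AssemblyEvent(
                            ev.age, r, Process.LOCAL_EXTINCTION,
                            branch_index=b.branch_index))
                elif ev.move_class == AnaClass.BIOME_SHIFT:
                    to = space[ev.to_states[0]]
                    gained = has_focal(to.biome) and not has_focal(frm.biome)
                    lost = has_focal(frm.biome) and not has_focal(to.biome)
                    if gained or lost:
                        proc = (Process.NICHE_EXPANSION if gained
                                else Process.NICHE_CONTRACTION)
                        for r in frm.regions:
                            out.append(AssemblyEvent(
                                ev.age, r, proc, branch_index=b.branch_index))
                elif ev.move_class == AnaClass.EXTINCTION:
                    if frm.range_size == 1 and has_focal(frm.biome):
                        out.append(AssemblyEvent(
                            ev.age, frm.regions[0], Process.LOCAL_EXTINCTION,
                            branch_index=b.branch_index))
    return out


def assembly_events_to_frame(
    events_per_replicate: Iterable[Sequence[AssemblyEvent]],
) -> pd.DataFrame:
    """Long-format table: replicate, age, region, process, branch_index."""
    rows = []
    for rep, events in enumerate(events_per_replicate):
        for ev in events:
            rows.append((rep, ev.age, ev.region, ev.process, ev.detail,
                         ev.branch_index))
    return pd.DataFrame(
        rows, columns=["replicate", "age", "region", "process", "detail",
                       "branch_index"])
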