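"""Compound range x biome state space for joint biogeographic modelling.

A lineage's character is a *compound state*: a nonempty geographic range
(a set of regions, encoded as a bitmask) together with a biome-occupancy
flag.  Biome occupancy takes three values -- nonalpine only (``a``),
alpine only (``A``), or both (``Aa``) -- and is uniform across all regions
in the range, i.e. a biome shift applies to every occupied region at once.

Ranges are constrained: a legal range has at most ``max_range_size``
regions and induces a connected subgraph of the region adjacency matrix
(the usual DEC-style adjacency constraint).  Direct shifts between the two
pure biome states never occur; a lineage must pass through the mixed
``Aa`` state, so "alpine" and "nonalpine" are two anagenetic steps apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Biome",
    "RegionSet",
    "CompoundState",
    "StateSpace",
    "CladoClass",
    "AnaClass",
    "build_state_space",
    "cladogenetic_outcomes",
    "anagenetic_neighbors",
]


class Biome(IntEnum):
    """Biome occupancy flag; canonical order NONALPINE < ALPINE < BOTH."""

    NONALPINE = 0  # "a"
    ALPINE = 1     # "A"
    BOTH = 2       # "Aa"

    @property
    def symbol(self) -> str:
        return {Biome.NONALPINE: "a", Biome.ALPINE: "A", Biome.BOTH: "Aa"}[self]

    @property
    def has_alpine(self) -> bool:
        return self in (Biome.ALPINE, Biome.BOTH)

    @property
    def has_nonalpine(self) -> bool:
        return self in (Biome.NONALPINE, Biome.BOTH)


class CladoClass:
    """Cladogenetic event classes."""

    WITHIN_REGION = "WITHIN_REGION"
    BETWEEN_REGION = "BETWEEN_REGION"


class AnaClass:
    """Anagenetic move classes (plus the simulator's lineage-death marker)."""

    RANGE_EXPANSION = "RANGE_EXPANSION"
    RANGE_CONTRACTION = "RANGE_CONTRACTION"
    BIOME_SHIFT = "BIOME_SHIFT"
    EXTINCTION = "EXTINCTION"  # lineage death of a single-region endemic


@dataclass(frozen=True)
class RegionSet:
    """Named regions with a symmetric adjacency relation.

    Parameters
    ----------
    labels:
        Ordered region names; region ``i`` corresponds to bit ``i`` in
        range bitmasks.
    adjacency:
        Symmetric boolean matrix with an empty diagonal; ``adjacency[i, j]``
        is True when regions ``i`` and ``j`` share a dispersal border.
    """

    labels: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        adj = np.asarray(self.adjacency, dtype=bool)
        if len(labels) == 0:
            raise ValueError("region list must be nonempty")
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if adj.shape != (len(labels), len(labels)):
            raise ValueError("adjacency shape does not match label count")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency diagonal must be empty")
        adj = adj.copy()
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_pairs(cls, labels: Sequence[str],
                   pairs: Iterable[tuple[str, str]]) -> "RegionSet":
        """Build from a list of adjacent label pairs (config-file form)."""
        idx = {lab: i for i, lab in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=bool)
        for a, b in pairs:
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
        return cls(tuple(labels), adj)

    @classmethod
    def complete(cls, labels: Sequence[str]) -> "RegionSet":
        adj = ~np.eye(len(labels), dtype=bool)
        return cls(tuple(labels), adj)

    @classmethod
    def from_config(cls, path) -> "RegionSet":
        """Read ``{"labels": [...], "adjacent": [[a, b], ...]}`` JSON."""
        with open(path) as fh:
            cfg = json.load(fh)
        return cls.from_pairs(cfg["labels"], [tuple(p) for p in cfg["adjacent"]])


#: Default region set mirroring the study system: five Northern-Hemisphere
#: mountain systems plus the boreal-arctic ecozone.  The boreal-arctic
#: region borders every mountain system; the mid-latitude systems form an
#: Asian-to-European chain; western North America touches only the
#: boreal-arctic.
NORTHERN_HEMISPHERE_REGIONS = RegionSet.from_pairs(
    ("THH", "TianshanPamir", "IranoTuranianCaucasus", "EuropeanAlps",
     "WesternNorthAmerica", "BorealArctic"),
    [
        ("BorealArctic", "THH"),
        ("BorealArctic", "TianshanPamir"),
        ("BorealArctic", "IranoTuranianCaucasus"),
        ("BorealArctic", "EuropeanAlps"),
        ("BorealArctic", "WesternNorthAmerica"),
        ("THH", "TianshanPamir"),
        ("TianshanPamir", "IranoTuranianCaucasus"),
        ("IranoTuranianCaucasus", "EuropeanAlps"),
    ],
)


@dataclass(frozen=True, order=True)
class CompoundState:
    """A geographic range (bitmask over regions) plus a biome flag."""

    range_mask: int
    biome: Biome

    def __post_init__(self):
        if self.range_mask <= 0:
            raise ValueError("range must be nonempty")
        object.__setattr__(self, "biome", Biome(self.biome))

    @property
    def regions(self) -> tuple[int, ...]:
        """Indices of occupied regions, ascending."""
        m, out, i = self.range_mask, [], 0
        while m:
            if m & 1:
                out.append(i)
            m >>= 1
            i += 1
        return tuple(out)

    @property
    def range_size(self) -> int:
        return bin(self.range_mask).count("1")

    def label(self, regions: RegionSet) -> str:
        names = "+".join(regions.labels[i] for i in self.regions)
        return f"{names}|{self.biome.symbol}"


def _mask_connected(mask: int, adjacency: np.ndarray) -> bool:
    """Is the set of regions in ``mask`` connected under ``adjacency``?"""
    members = [i for i in range(adjacency.shape[0]) if mask >> i & 1]
    if len(members) <= 1:
        return True
    seen = {members[0]}
    stack = [members[0]]
    memberset = set(members)
    while stack:
        u = stack.pop()
        for v in memberset - seen:
            if adjacency[u, v]:
                seen.add(v)
                stack.append(v)
    return seen == memberset


_BIOME_ORDER = (Biome.NONALPINE, Biome.ALPINE, Biome.BOTH)

# Anagenetic biome moves: pure states reach BOTH; BOTH reaches either pure
# state; the two pure states are never one step apart.
_BIOME_SHIFTS = {
    Biome.NONALPINE: (Biome.BOTH,),
    Biome.ALPINE: (Biome.BOTH,),
    Biome.BOTH: (Biome.NONALPINE, Biome.ALPINE),
}


@dataclass(frozen=True)
class StateSpace:
    """Indexed enumeration of all legal compound states.

    States are ordered by (range size, range bitmask, biome) so indices are
    reproducible across runs and serialized files.
    """

    regions: RegionSet
    max_range_size: int
    states: tuple[CompoundState, ...] = field(default=())
    index: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def __contains__(self, state: CompoundState) -> bool:
        return state in self.index

    def __getitem__(self, i: int) -> CompoundState:
        return self.states[i]

    def index_of(self, state: CompoundState) -> int:
        try:
            return self.index[state]
        except KeyError:
            raise KeyError(f"state {state} not in state space") from None

    def valid_mask(self, mask: int) -> bool:
        return (
            mask > 0
            and bin(mask).count("1") <= self.max_range_size
            and _mask_connected(mask, self.regions.adjacency)
        )

    def state(self, region_labels: Iterable[str], biome: Biome) -> CompoundState:
        """Convenience constructor from region labels."""
        idx = {lab: i for i, lab in enumerate(self.regions.labels)}
        mask = 0
        for lab in region_labels:
            mask |= 1 << idx[lab]
        return CompoundState(mask, biome)


def build_state_space(regions: RegionSet, max_range_size: int = 4) -> StateSpace:
    """Enumerate every legal (range, biome) pair.

    A range is legal when nonempty, of size at most ``max_range_size`` and
    connected under the region adjacency.  Each legal range is crossed with
    the three biome states.
    """
    if max_range_size < 1:
        raise ValueError("max_range_size must be >= 1")
    n = regions.n
    masks = [
        m for m in range(1, 1 << n)
        if bin(m).count("1") <= max_range_size
        and _mask_connected(m, regions.adjacency)
    ]
    masks.sort(key=lambda m: (bin(m).count("1"), m))
    states = tuple(
        CompoundState(m, b) for m in masks for b in _BIOME_ORDER
    )
    index = {s: i for i, s in enumerate(states)}
    return StateSpace(regions=regions, max_range_size=max_range_size,
                      states=states, index=index)


def _connected_bipartitions(mask: int, adjacency: np.ndarray) -> list[tuple[int, int]]:
    """Unordered splits of ``mask`` into two nonempty connected sub-masks."""
    members = [i for i in range(adjacency.shape[0]) if mask >> i & 1]
    if len(members) < 2:
        return []
    anchor = members[0]
    out = []
    rest = members[1:]
    for k in range(0, len(rest)):
        for combo in combinations(rest, k):
            left = (1 << anchor) | sum(1 << i for i in combo)
            right = mask ^ left
            if right == 0:
                continue
            if _mask_connected(left, adjacency) and _mask_connected(right, adjacency):
                out.append((min(left, right), max(left, right)))
    return sorted(set(out))


def cladogenetic_outcomes(
    state: CompoundState, space: StateSpace
) -> list[tuple[CompoundState, CompoundState, str, int | None]]:
    """Legal daughter-state pairs of ``state`` at a speciation event.

    Returns tuples ``(left, right, event_class, region)`` in canonical
    order; daughters are unordered (listed once, with ``left <= right`` by
    state index).  ``region`` is the budding region for within-region
    events and ``None`` for between-region (vicariant) splits.

    WITHIN_REGION(r): one daughter keeps the parent state, the other is
    the single-region state ``({r}, b')``.  From a pure-biome parent the
    bud inherits the parent biome; from a mixed (``Aa``) parent the bud
    may take any of the three biome values -- this is the pathway by which
    an alpine endemic can "bud off" a widespread mixed-biome ancestor
    (subset speciation).

    BETWEEN_REGION: the range splits into two connected, nonempty
    sub-ranges; both daughters inherit the parent biome.
    """
    if state not in space:
        raise KeyError(f"state {state} not in state space")
    out: list[tuple[CompoundState, CompoundState, str, int | None]] = []
    if state.biome == Biome.BOTH:
        bud_biomes = (Biome.NONALPINE, Biome.ALPINE, Biome.BOTH)
    else:
        bud_biomes = (state.biome,)
    for r in state.regions:
        seen = set()
        for b in bud_biomes:
            bud = CompoundState(1 << r, b)
            pair = tuple(sorted((state, bud), key=space.index_of))
            if pair not in seen:
                seen.add(pair)
                out.append((pair[0], pair[1], CladoClass.WITHIN_REGION, r))
    for left_mask, right_mask in _connected_bipartitions(
        state.range_mask, space.regions.adjacency
    ):
        left = CompoundState(left_mask, state.biome)
        right = CompoundState(right_mask, state.biome)
        pair = tuple(sorted((left, right), key=space.index_of))
        out.append((pair[0], pair[1], CladoClass.BETWEEN_REGION, None))
    return out


def anagenetic_neighbors(
    state: CompoundState, space: StateSpace
) -> list[tuple[CompoundState, str]]:
    """Single-step anagenetic moves from ``state``.

    Range expansion adds one region adjacent to the current range (subject
    to the size cap and connectivity), range contraction drops one region
    leaving a valid remainder, and biome shifts move between a pure biome
    and the mixed state.  Range moves and biome moves never combine in a
    single step, and the two pure biomes are never direct neighbours.
    """
    if state not in space:
        raise KeyError(f"state {state} not in state space")
    adj = space.regions.adjacency
    n = space.regions.n
    out: list[tuple[CompoundState, str]] = []
    occupied = state.regions
    for j in range(n):
        if state.range_mask >> j & 1:
            continue
        if any(adj[i, j] for i in occupied):
            new_mask = state.range_mask | (1 << j)
            if space.valid_mask(new_mask):
                out.append((CompoundState(new_mask, state.biome),
                            AnaClass.RANGE_EXPANSION))
    if state.range_size > 1:
        for r in occupied:
            new_mask = state.range_mask & ~(1 << r)
            if space.valid_mask(new_mask):
                out.append((CompoundState(new_mask, state.biome),
                            AnaClass.RANGE_CONTRACTION))
    for b in _BIOME_SHIFTS[state.biome]:
        out.append((CompoundState(state.range_mask, b), AnaClass.BIOME_SHIFT))
    return out
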