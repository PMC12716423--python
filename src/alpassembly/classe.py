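"""Compound-state ClaSSE engine: likelihood, simulation, stochastic mapping.

The model couples cladogenetic state-dependent speciation-extinction
(ClaSSE) with the compound range x biome state space.  Its free rates are
per-region within-region speciation rates, a single between-region
(vicariant) speciation rate, a base dispersal (range-expansion) rate, a
single biome-transition rate, and per-region local-extinction
(extirpation) rates; incomplete sampling enters through a clade sampling
fraction rho.

Along a branch the standard coupled ClaSSE system is integrated tipward to
rootward, with E_i(t) the probability that a lineage in state i at time t
before the present leaves no sampled descendants and D_i(t) the density of
the observed subtree:

    dE_i/dt = mu_i - (Lam_i + Q_i + mu_i) E_i + sum_j Q_ij E_j
              + sum_{o=(j,k)} r_o E_j E_k
    dD_i/dt = -(Lam_i + Q_i + mu_i) D_i + sum_j Q_ij D_j
              + sum_{o=(j,k)} r_o (D_j E_k + D_k E_j)

where cladogenetic outcomes o are unordered daughter pairs with rate r_o,
Lam_i = sum of r_o over outcomes of i, and Q_i the total anagenetic rate.
At an observed node, D_i = sum_o r_o (D^L_j D^R_k + D^L_k D^R_j) / 2.

Stochastic mapping draws node states from their exact joint conditional
distribution (using per-branch solution operators of the linear D system)
and then fills branches by rejection sampling of the anagenetic process
augmented with hidden-cladogenesis transitions at rate r_o E_k(t), i.e.
real speciations whose sibling leaves no sampled descendants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import minimize

from .history import BranchHistory, Event, EventKind, MappedHistory
from .state_space import (
    AnaClass,
    Biome,
    CladoClass,
    CompoundState,
    StateSpace,
    anagenetic_neighbors,
    cladogenetic_outcomes,
)

__all__ = [
    "ClasseParameters",
    "GeneratorSet",
    "build_generators",
    "classe_loglik",
    "marginal_ancestral_states",
    "simulate_clade",
    "stochastic_maps",
    "sample_branch_path",
    "fit_lambda_within",
    "CladeExtinctError",
    "MappingError",
    "TreeIndex",
    "read_tree",
    "read_tip_data",
    "write_tip_data",
]


class CladeExtinctError(RuntimeError):
    """The simulated clade died out before reaching the present."""


class MappingError(RuntimeError):
    """Branch rejection sampling fell below the acceptance floor."""


@dataclass(frozen=True)
class ClasseParameters:
    """Rates of the compound-state model (events / lineage / Ma).

    ``lambda_within`` and ``extirpation`` may be scalars (shared across
    regions) or one value per region.
    """

    lambda_within: float | tuple[float, ...]
    lambda_between: float
    dispersal: float
    biome_rate: float
    extirpation: float | tuple[float, ...]
    sampling_fraction: float = 1.0

    def __post_init__(self):
        for name in ("lambda_within", "lambda_between", "dispersal",
                     "biome_rate", "extirpation"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if (v < 0).any():
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling_fraction must be in (0, 1]")

    def lambda_within_per_region(self, n: int) -> np.ndarray:
        v = np.atleast_1d(np.asarray(self.lambda_within, dtype=float))
        if v.size == 1:
            return np.full(n, v[0])
        if v.size != n:
            raise ValueError("lambda_within length does not match regions")
        return v.copy()

    def extirpation_per_region(self, n: int) -> np.ndarray:
        v = np.atleast_1d(np.asarray(self.extirpation, dtype=float))
        if v.size == 1:
            return np.full(n, v[0])
        if v.size != n:
            raise ValueError("extirpation length does not match regions")
        return v.copy()


@dataclass
class GeneratorSet:
    """Numeric generators over state indices.

    ``Q`` holds anagenetic rates (off-diagonal; the diagonal is zero and
    total loss rates are applied explicitly).  Cladogenetic outcomes are a
    flat sparse list of unordered daughter pairs (left <= right by index)
    with their full outcome rate, event class and budding region.
    """

    space: StateSpace
    Q: np.ndarray
    mu: np.ndarray
    out_parent: np.ndarray
    out_left: np.ndarray
    out_right: np.ndarray
    out_rate: np.ndarray
    out_class: tuple[str, ...]
    out_region: np.ndarray
    q_move: dict = field(default_factory=dict)   # (i, j) -> move class

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.q_tot = self.Q.sum(axis=1)
        n = self.space.n_states
        self.lambda_tot = np.bincount(
            self.out_parent, weights=self.out_rate, minlength=n)
        self.outcomes_of = [
            np.flatnonzero(self.out_parent == i) for i in range(n)]

    @property
    def n_states(self) -> int:
        return self.space.n_states


def build_generators(params: ClasseParameters, space: StateSpace) -> GeneratorSet:
    """Assemble Q, the cladogenetic outcome list and mu for a state space.

    Range expansion into region j proceeds at ``dispersal`` times the
    number of occupied regions adjacent to j; contraction dropping r at
    ``extirpation[r]`` (when the remainder is a valid range); each allowed
    biome shift at ``biome_rate``.  The within-region speciation rate of
    region r is split equally over that region's distinct outcomes, and
    the between-region rate equally over the valid range bipartitions.
    Whole-lineage extinction applies only to single-region states.
    """
    nreg = space.regions.n
    lam_w = params.lambda_within_per_region(nreg)
    ext = params.extirpation_per_region(nreg)
    n = space.n_states
    Q = np.zeros((n, n))
    q_move: dict = {}
    mu = np.zeros(n)
    adj = space.regions.adjacency

    for i, s in enumerate(space.states):
        for target, move in anagenetic_neighbors(s, space):
            j = space.index_of(target)
            if move == AnaClass.RANGE_EXPANSION:
                new_region = (target.range_mask ^ s.range_mask).bit_length() - 1
                n_src = sum(1 for r in s.regions if adj[r, new_region])
                Q[i, j] = params.dispersal * n_src
            elif move == AnaClass.RANGE_CONTRACTION:
                dropped = (s.range_mask ^ target.range_mask).bit_length() - 1
                Q[i, j] = ext[dropped]
            else:
                Q[i, j] = params.biome_rate
            q_move[(i, j)] = move
        if s.range_size == 1:
            mu[i] = ext[s.regions[0]]

    op, ol, orr, orate, oclass, oregion = [], [], [], [], [], []
    for i, s in enumerate(space.states):
        outs = cladogenetic_outcomes(s, space)
        within = [o for o in outs if o[2] == CladoClass.WITHIN_REGION]
        between = [o for o in outs if o[2] == CladoClass.BETWEEN_REGION]
        per_region: dict[int, list] = {}
        for o in within:
            per_region.setdefault(o[3], []).append(o)
        for r, group in per_region.items():
            rate = lam_w[r] / len(group)
            for left, right, _, _ in group:
                op.append(i)
                ol.append(space.index_of(left))
                orr.append(space.index_of(right))
                orate.append(rate)
                oclass.append(CladoClass.WITHIN_REGION)
                oregion.append(r)
        if between:
            rate = params.lambda_between / len(between)
            for left, right, _, _ in between:
                op.append(i)
                ol.append(space.index_of(left))
                orr.append(space.index_of(right))
                orate.append(rate)
                oclass.append(CladoClass.BETWEEN_REGION)
                oregion.append(-1)

    return GeneratorSet(
        space=space, Q=Q, mu=mu,
        out_parent=np.asarray(op, dtype=int),
        out_left=np.asarray(ol, dtype=int),
        out_right=np.asarray(orr, dtype=int),
        out_rate=np.asarray(orate, dtype=float),
        out_class=tuple(oclass),
        out_region=np.asarray(oregion, dtype=int),
        q_move=q_move,
    )


# ---------------------------------------------------------------------------
# tree indexing

class TreeIndex:
    """Array view of a rooted binary tree; node ids are preorder indices."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        self.n_nodes = len(nodes)
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.blen = np.zeros(self.n_nodes)
        self.children: list[tuple[int, ...]] = [()] * self.n_nodes
        self.label: list[str | None] = [None] * self.n_nodes
        depth = np.zeros(self.n_nodes)
        for i, nd in enumerate(nodes):
            kids = nd.child_nodes()
            if kids and len(kids) != 2:
                raise ValueError("tree must be binary")
            self.children[i] = tuple(ids[id(k)] for k in kids)
            if nd.parent_node is not None:
                p = ids[id(nd.parent_node)]
                self.parent[i] = p
                if nd.edge.length is None or nd.edge.length <= 0:
                    raise ValueError("branch lengths must be positive")
                self.blen[i] = nd.edge.length
                depth[i] = depth[p] + self.blen[i]
            if nd.taxon is not None:
                self.label[i] = nd.taxon.label
        self.tips = [i for i in range(self.n_nodes) if not self.children[i]]
        self.root_age = float(depth[self.tips].max())
        self.age = self.root_age - depth
        # time-calibrated use assumes an ultrametric tree
        if np.any(np.abs(self.age[self.tips]) > 1e-6 * max(self.root_age, 1.0)):
            raise ValueError("tree is not ultrametric within tolerance")
        self.age[self.tips] = 0.0
        self.postorder = self._postorder()

    def _postorder(self) -> list[int]:
        out, stack = [], [0]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        out.reverse()
        return out


def read_tree(path) -> dendropy.Tree:
    """Read a Newick tree with branch lengths in Ma."""
    return dendropy.Tree.get(path=str(path), schema="newick")


def read_tip_data(path, space: StateSpace) -> dict[str, set[int]]:
    """Read tip assignments from TSV: tip <TAB> region1+region2 <TAB> biome.

    Biome is one of ``a`` (nonalpine), ``A`` (alpine), ``Aa`` (both), or
    ``?`` for fully ambiguous tips.
    """
    sym = {"a": Biome.NONALPINE, "A": Biome.ALPINE, "Aa": Biome.BOTH}
    tips: dict[str, set[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, ranges, biome = line.split("\t")
            if ranges == "?" or biome == "?":
                tips[name] = set(range(space.n_states))
            else:
                st = space.state(ranges.split("+"), sym[biome])
                tips[name] = {space.index_of(st)}
    return tips


def write_tip_data(tips: dict[str, set[int]], space: StateSpace, path) -> None:
    with open(path, "w") as fh:
        for name, states in tips.items():
            if len(states) == 1:
                s = space[next(iter(states))]
                ranges = "+".join(space.regions.labels[r] for r in s.regions)
                fh.write(f"{name}\t{ranges}\t{s.biome.symbol}\n")
            else:
                fh.write(f"{name}\t?\t?\n")


# ---------------------------------------------------------------------------
# ODE right-hand sides

class _Rates:
    """Precomputed arrays for fast RHS evaluation."""

    def __init__(self, gen: GeneratorSet):
        self.n = gen.n_states
        self.Q = gen.Q
        self.mu = gen.mu
        self.loss = gen.lambda_tot + gen.q_tot + gen.mu
        self.op = gen.out_parent
        self.ol = gen.out_left
        self.orr = gen.out_right
        self.orate = gen.out_rate

    def e_rhs(self, _t, E):
        S = np.bincount(self.op, weights=self.orate * E[self.ol] * E[self.orr],
                        minlength=self.n)
        return self.mu - self.loss * E + self.Q @ E + S

    def d_rhs(self, D, E):
        S = np.bincount(
            self.op,
            weights=self.orate * (D[self.ol] * E[self.orr]
                                  + D[self.orr] * E[self.ol]),
            minlength=self.n)
        return -self.loss * D + self.Q @ D + S

    def joint_rhs(self, t, y):
        E, D = y[: self.n], y[self.n:]
        return np.concatenate([self.e_rhs(t, E), self.d_rhs(D, E)])

    def b_matrix(self, E):
        """Linear operator of the D system given E: dD/dt = B D."""
        B = self.Q - np.diag(self.loss)
        np.add.at(B, (self.op, self.ol), self.orate * E[self.orr])
        np.add.at(B, (self.op, self.orr), self.orate * E[self.ol])
        return B

    def node_combine(self, DL, DR):
        contrib = 0.5 * self.orate * (DL[self.ol] * DR[self.orr]
                                      + DL[self.orr] * DR[self.ol])
        return np.bincount(self.op, weights=contrib, minlength=self.n)


def _tip_vectors(ti: TreeIndex, tips: dict[str, set[int]], n: int,
                 rho: float) -> dict[int, np.ndarray]:
    out = {}
    for i in ti.tips:
        lab = ti.label[i]
        if lab is None or lab not in tips:
            raise ValueError(f"tip node {i} ({lab!r}) has no state data")
        compat = tips[lab]
        if not compat:
            raise ValueError(f"tip {lab!r} has an empty compatible-state set")
        v = np.zeros(n)
        v[sorted(compat)] = rho
        out[i] = v
    return out


@dataclass
class _Pass:
    """Everything the likelihood pass learned (reused by mapping)."""

    ti: TreeIndex
    rates: _Rates
    D_bottom: dict[int, np.ndarray]
    D_top: dict[int, np.ndarray]
    K: dict[int, np.ndarray]
    E_sol: object
    E_root: np.ndarray
    D_root: np.ndarray
    loglik: float
    prop_cache: dict = field(default_factory=dict)


def _solve_E(rates: _Rates, rho: float, root_age: float,
             rtol: float, atol: float):
    E0 = np.full(rates.n, 1.0 - rho)
    sol = solve_ivp(rates.e_rhs, (0.0, root_age * (1 + 1e-12) + 1e-12), E0,
                    method="LSODA", rtol=rtol, atol=atol, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"E integration failed: {sol.message}")
    return sol


def _branch_propagator_grid(rates: _Rates, E_sol, a0: float, a1: float,
                            n_seg: int) -> np.ndarray:
    """Propagator K with D_top = K @ D_bottom via piecewise-constant E."""
    K = np.eye(rates.n)
    edges = np.linspace(a0, a1, n_seg + 1)
    for s in range(n_seg):
        mid = 0.5 * (edges[s] + edges[s + 1])
        B = rates.b_matrix(E_sol.sol(mid))
        K = expm(B * (edges[s + 1] - edges[s])) @ K
    return K


def _likelihood_pass(
    tree: dendropy.Tree | TreeIndex,
    tips: dict[str, set[int]],
    gen: GeneratorSet,
    sampling_fraction: float = 1.0,
    method: str = "ode",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_grid: int = 200,
    compute_K: bool = False,
    k_segments: int = 25,
) -> _Pass:
    ti = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    rates = _Rates(gen)
    n = rates.n
    rho = float(sampling_fraction)
    D_bottom = _tip_vectors(ti, tips, n, rho)
    D_top: dict[int, np.ndarray] = {}
    K: dict[int, np.ndarray] = {}
    logscale = 0.0
    E_sol = _solve_E(rates, rho, ti.root_age, rtol, atol)
    E_node: dict[int, np.ndarray] = {i: np.full(n, 1.0 - rho) for i in ti.tips}

    if method == "grid":
        # cached per-interval propagators on a uniform global age grid
        edges = np.linspace(0.0, ti.root_age, n_grid + 1)
        cache: dict[int, np.ndarray] = {}

        def interval_prop(k):
            if k not in cache:
                mid = 0.5 * (edges[k] + edges[k + 1])
                B = rates.b_matrix(E_sol.sol(mid))
                cache[k] = expm(B * (edges[k + 1] - edges[k]))
            return cache[k]

        def partial(D, a0, a1):
            if a1 - a0 <= 0:
                return D
            mid = 0.5 * (a0 + a1)
            B = rates.b_matrix(E_sol.sol(mid))
            return expm(B * (a1 - a0)) @ D

        def propagate(D, a0, a1):
            # first grid edge strictly above a0 / last edge at or below a1
            lo = int(np.searchsorted(edges, a0, side="right"))
            hi = int(np.searchsorted(edges, a1, side="right")) - 1
            if hi < lo:  # no whole interval inside the branch
                return partial(D, a0, a1)
            D = partial(D, a0, edges[lo])
            for k in range(lo, hi):
                D = interval_prop(k) @ D
            return partial(D, edges[hi], a1)
    elif method != "ode":
        raise ValueError("method must be 'ode' or 'grid'")

    for i in ti.postorder:
        if ti.children[i]:
            c1, c2 = ti.children[i]
            D_bottom[i] = rates.node_combine(D_top[c1], D_top[c2])
            # E at this node was stored when its first child branch was
            # integrated (both daughters give the same E on an
            # ultrametric tree)
        if ti.parent[i] >= 0:
            a0, a1 = ti.age[i], ti.age[ti.parent[i]]
            if method == "ode":
                y0 = np.concatenate([E_node[i], D_bottom[i]])
                sol = solve_ivp(rates.joint_rhs, (a0, a1), y0, method="LSODA",
                                rtol=rtol, atol=atol)
                if not sol.success:
                    raise RuntimeError(
                        f"branch integration failed: {sol.message}")
                E_top, D = sol.y[:n, -1], sol.y[n:, -1]
            else:
                D = propagate(D_bottom[i], a0, a1)
                E_top = E_sol.sol(a1)
            s = float(D.max())
            if not np.isfinite(s) or s <= 0:
                raise RuntimeError(
                    "non-finite or all-zero branch likelihood; check tip "
                    "data and rates")
            D_top[i] = D / s
            logscale += math.log(s)
            p = ti.parent[i]
            if p not in E_node:
                E_node[p] = E_top
            if compute_K:
                K[i] = _branch_propagator_grid(rates, E_sol, a0, a1,
                                               k_segments)

    D_root = D_bottom[0]
    E_root = np.asarray(E_sol.sol(ti.root_age))
    return _Pass(ti=ti, rates=rates, D_bottom=D_bottom, D_top=D_top, K=K,
                 E_sol=E_sol, E_root=E_root, D_root=D_root,
                 loglik=logscale)


def _root_likelihood(pas: _Pass, gen: GeneratorSet,
                     root_weighting, condition_on_survival: bool) -> float:
    D = pas.D_root
    n = D.size
    if isinstance(root_weighting, (int, np.integer)):
        w = np.zeros(n)
        w[int(root_weighting)] = 1.0
    elif root_weighting == "uniform":
        w = np.full(n, 1.0 / n)
    elif root_weighting == "fitzjohn":
        tot = D.sum()
        if tot <= 0:
            raise RuntimeError("all-zero root likelihood")
        w = D / tot
    else:
        raise ValueError("root_weighting must be 'fitzjohn', 'uniform' or "
                         "a state index")
    v = D.copy()
    if condition_on_survival:
        lam = gen.lambda_tot
        denom = lam * (1.0 - pas.E_root) ** 2
        ok = denom > 0
        v = np.divide(v, denom, out=np.zeros_like(v), where=ok)
    L = float(w @ v)
    if L <= 0 or not np.isfinite(L):
        raise RuntimeError("non-positive likelihood at root")
    return math.log(L) + pas.loglik


def classe_loglik(
    tree,
    tips: dict[str, set[int]],
    gen: GeneratorSet,
    sampling_fraction: float = 1.0,
    condition_on_survival: bool = True,
    root_weighting="fitzjohn",
    method: str = "ode",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_grid: int = 200,
) -> float:
    """Log-likelihood of tip data under the compound-state model.

    ``method='ode'`` integrates each branch with an adaptive stiff/
    non-stiff solver; ``method='grid'`` propagates D with products of
    per-interval matrix exponentials on a global age grid of ``n_grid``
    intervals (much faster inside optimization loops, accurate to the
    grid resolution).  The root uses likelihood-proportional (FitzJohn)
    state weights by default, with uniform and fixed-state options, and
    optionally conditions on survival of both root daughter lineages.
    """
    pas = _likelihood_pass(tree, tips, gen, sampling_fraction, method,
                           rtol, atol, n_grid)
    return _root_likelihood(pas, gen, root_weighting, condition_on_survival)


def marginal_ancestral_states(
    tree,
    tips: dict[str, set[int]],
    gen: GeneratorSet,
    sampling_fraction: float = 1.0,
    root_weighting="fitzjohn",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    k_segments: int = 100,
) -> dict[int, np.ndarray]:
    """Exact marginal posterior state probabilities at every node.

    Uses the downpass partials together with an uppass through per-branch
    solution operators of the linear D system.  Node ids are preorder
    indices of the tree.
    """
    pas = _likelihood_pass(tree, tips, gen, sampling_fraction, "ode",
                           rtol, atol, compute_K=True, k_segments=k_segments)
    ti, rates = pas.ti, pas.rates
    n = rates.n
    D = pas.D_root
    if isinstance(root_weighting, (int, np.integer)):
        w = np.zeros(n)
        w[int(root_weighting)] = 1.0
    elif root_weighting == "uniform":
        w = np.full(n, 1.0 / n)
    else:
        w = D / D.sum()
    F: dict[int, np.ndarray] = {0: w}
    marg = {0: _normalize(w * D)}
    order = [i for i in range(ti.n_nodes)]  # preorder
    for p in order:
        if not ti.children[p]:
            continue
        c1, c2 = ti.children[p]
        for c, sib in ((c1, c2), (c2, c1)):
            G = _daughter_uppass(rates, F[p], pas.D_top[sib])
            F[c] = pas.K[c].T @ G
            marg[c] = _normalize(F[c] * pas.D_bottom[c])
    return marg


def _normalize(v: np.ndarray) -> np.ndarray:
    t = v.sum()
    if t <= 0:
        raise RuntimeError("zero marginal normalizer")
    return v / t


def _daughter_uppass(rates: _Rates, Fp: np.ndarray,
                     D_sib_top: np.ndarray) -> np.ndarray:
    """Uppass partial at the top of one daughter branch."""
    G = np.zeros(rates.n)
    wgt = 0.5 * rates.orate * Fp[rates.op]
    np.add.at(G, rates.ol, wgt * D_sib_top[rates.orr])
    np.add.at(G, rates.orr, wgt * D_sib_top[rates.ol])
    return G


# ---------------------------------------------------------------------------
# forward simulation

def simulate_clade(
    gen: GeneratorSet,
    root_state: int | CompoundState,
    max_age: float,
    seed: int,
    sampling_fraction: float = 1.0,
    max_lineages: int = 20000,
    min_tips: int = 2,
):
    """Gillespie forward simulation of the compound-state process.

    Starts one lineage at ``max_age`` in ``root_state`` and simulates
    competing exponential clocks for every anagenetic move, cladogenetic
    outcome and lineage extinction until the present.  Returns the pruned
    extant sampled tree (dendropy), the full true history (extinct
    lineages retained; branch/child ids are lineage creation order) and
    tip data.  The history's ``extra`` carries the simulator's own
    assembly-event tally, counted independently of the classifier.

    Raises :class:`CladeExtinctError` when fewer than ``min_tips``
    sampled lineages reach the present.
    """
    space = gen.space
    if max_age <= 0:
        raise ValueError("max_age must be positive")
    if isinstance(root_state, CompoundState):
        root_state = space.index_of(root_state)
    rng = np.random.default_rng(seed)
    total_rate = gen.lambda_tot + gen.q_tot + gen.mu
    q_targets = [np.flatnonzero(gen.Q[i]) for i in range(gen.n_states)]

    # lineage records
    birth_age = [max_age]
    parent = [-1]
    state = [int(root_state)]
    birth_state = [int(root_state)]
    events: list[list[Event]] = [[]]
    end_age = [None]
    children: list[list[int]] = [[]]
    alive = {0}
    tally: dict[str, int] = {}

    def count(process: str, region: int, k: int = 1):
        key = f"{process}:{region}"
        tally[key] = tally.get(key, 0) + k

    def tally_clado(s_idx: int, daughters: Sequence[int], _age: float):
        s = space[s_idx]
        if s.range_size == 1 and s.biome == Biome.ALPINE:
            count("IN_SITU_SPECIATION", s.regions[0])
            return
        if not s.biome.has_alpine:
            return
        for di in daughters:
            d = space[di]
            if (d.range_size == 1 and d.biome == Biome.ALPINE
                    and s.range_mask >> d.regions[0] & 1 and di != s_idx):
                count("SUBSET_SPECIATION", d.regions[0])

    t = max_age
    while alive:
        rates = np.array([total_rate[state[i]] for i in sorted(alive)])
        live = sorted(alive)
        R = rates.sum()
        if R <= 0:
            break  # frozen: all live lineages persist to the present
        t = t - rng.exponential(1.0 / R)
        if t <= 0:
            break
        li = live[rng.choice(len(live), p=rates / R)]
        si = state[li]
        s = space[si]
        lam, qt, m = gen.lambda_tot[si], gen.q_tot[si], gen.mu[si]
        u = rng.random() * (lam + qt + m)
        if u < lam:
            # cladogenesis
            outs = gen.outcomes_of[si]
            probs = gen.out_rate[outs] / lam
            o = outs[rng.choice(len(outs), p=probs)]
            j, k = int(gen.out_left[o]), int(gen.out_right[o])
            if rng.random() < 0.5:
                j, k = k, j
            events[li].append(Event(
                age=t, kind=EventKind.CLADOGENETIC_NODE,
                move_class=gen.out_class[o], from_state=si,
                to_states=(j, k), state_changed=(j != si or k != si),
                extra=({"region": int(gen.out_region[o])}
                       if gen.out_region[o] >= 0 else {})))
            end_age[li] = t
            alive.discard(li)
            for ds in (j, k):
                birth_age.append(t)
                parent.append(li)
                state.append(ds)
                birth_state.append(ds)
                events.append([])
                end_age.append(None)
                children[li].append(len(birth_age) - 1)
                children.append([])
                alive.add(len(birth_age) - 1)
            tally_clado(si, (j, k), t)
            if len(birth_age) > max_lineages:
                raise RuntimeError(
                    f"simulation exceeded {max_lineages} lineages; "
                    "lower the rates or max_age")
        elif u < lam + qt:
            # anagenetic move
            tg = q_targets[si]
            probs = gen.Q[si, tg] / qt
            j = int(tg[rng.choice(len(tg), p=probs)])
            move = gen.q_move[(si, j)]
            events[li].append(Event(
                age=t, kind=EventKind.ANAGENETIC, move_class=move,
                from_state=si, to_states=(j,), state_changed=True))
            to = space[j]
            if move == AnaClass.RANGE_EXPANSION and s.biome.has_alpine:
                r = (to.range_mask ^ s.range_mask).bit_length() - 1
                count("COLONIZATION", r)
            elif move == AnaClass.RANGE_CONTRACTION and s.biome.has_alpine:
                r = (s.range_mask ^ to.range_mask).bit_length() - 1
                count("LOCAL_EXTINCTION", r)
            elif move == AnaClass.BIOME_SHIFT:
                if to.biome.has_alpine and not s.biome.has_alpine:
                    for r in s.regions:
                        count("NICHE_EXPANSION", r)
                elif s.biome.has_alpine and not to.biome.has_alpine:
                    for r in s.regions:
                        count("NICHE_CONTRACTION", r)
            state[li] = j
        else:
            # lineage extinction (single-region states only)
            events[li].append(Event(
                age=t, kind=EventKind.ANAGENETIC,
                move_class=AnaClass.EXTINCTION, from_state=si,
                to_states=(si,), state_changed=False))
            end_age[li] = t
            alive.discard(li)
            if s.biome.has_alpine:
                count("LOCAL_EXTINCTION", s.regions[0])

    for li in list(alive):
        end_age[li] = 0.0

    n_lin = len(birth_age)
    extant = [i for i in range(n_lin) if end_age[i] == 0.0]
    sampled = [i for i in extant
               if sampling_fraction >= 1.0 or rng.random() < sampling_fraction]
    if len(sampled) < min_tips:
        raise CladeExtinctError(
            f"only {len(sampled)} sampled extant lineages (need {min_tips})")

    branches = []
    for i in range(n_lin):
        start = birth_state[i]
        # walk the event chain to the branch end state
        st = start
        for ev in events[i]:
            if ev.kind != EventKind.CLADOGENETIC_NODE:
                st = ev.to_states[0]
        branches.append(BranchHistory(
            branch_index=i, parent_node=parent[i], child_node=i,
            start_age=birth_age[i], end_age=float(end_age[i]),
            start_state=start, end_state=st,
            events=events[i],
            label=f"t{i}" if i in set(sampled) else None,
        ))
    truth = MappedHistory(
        branches=branches,
        extra={"simulator_tally": tally, "seed": int(seed),
               "n_extant": len(extant), "n_sampled": len(sampled)},
    )

    tree = _prune_to_tree(birth_age, parent, children, end_age, set(sampled))
    tipdata = {f"t{i}": {state[i]} for i in sampled}
    return tree, truth, tipdata


def _prune_to_tree(birth_age, parent, children, end_age, keep: set[int]):
    """Build the dendropy tree spanning the kept extant lineages."""
    mark_cache: dict[int, bool] = {}
    for i in reversed(range(len(birth_age))):
        mark_cache[i] = (i in keep) or any(mark_cache[c] for c in children[i])

    def newick(i, stem_top_age):
        kept_kids = [c for c in children[i] if mark_cache[c]]
        if not kept_kids:
            return f"t{i}:{stem_top_age - end_age[i]:.10g}"
        if len(kept_kids) == 1:
            return newick(kept_kids[0], stem_top_age)
        parts = [newick(c, end_age[i]) for c in kept_kids]
        return f"({','.join(parts)}):{stem_top_age - end_age[i]:.10g}"

    # find the MRCA start: walk from the root lineage down while only one
    # child subtree holds kept tips
    root = 0
    while True:
        kept_kids = [c for c in children[root] if mark_cache[c]]
        if root in keep or len(kept_kids) != 1:
            break
        root = kept_kids[0]
    if root in keep and not children[root]:
        # clade that never branched: a single surviving lineage
        nwk = f"t{root}:{birth_age[root]:.10g};"
        return dendropy.Tree.get(data=nwk, schema="newick")
    if len(kept_kids) < 2:
        raise CladeExtinctError("fewer than two surviving subtrees")
    parts = [newick(c, end_age[root]) for c in children[root]
             if mark_cache[c]]
    nwk = f"({','.join(parts)});"
    return dendropy.Tree.get(data=nwk, schema="newick")


# ---------------------------------------------------------------------------
# stochastic mapping

def _branch_grid(rates: _Rates, gen: GeneratorSet, E_sol,
                 a0: float, a1: float, grid_points: int):
    """E and hidden-rate bounds on a per-branch age grid."""
    ages = np.linspace(a0, a1, grid_points)
    Eg = np.stack([np.asarray(E_sol.sol(a)) for a in ages])  # (G, n)
    # total hidden-speciation rate per state per grid point
    ht = np.zeros((grid_points, rates.n))
    contrib = gen.out_rate[None, :] * (Eg[:, gen.out_left]
                                       + Eg[:, gen.out_right])
    for g in range(grid_points):
        ht[g] = np.bincount(gen.out_parent, weights=contrib[g],
                            minlength=rates.n)
    bound = 1.2 * (ht.max(axis=0) + rates.Q.sum(axis=1)) + 1e-12
    return ages, Eg, bound


def _interp_E(ages, Eg, a):
    if a <= ages[0]:
        return Eg[0]
    if a >= ages[-1]:
        return Eg[-1]
    g = int(np.searchsorted(ages, a)) - 1
    w = (a - ages[g]) / (ages[g + 1] - ages[g])
    return Eg[g] * (1 - w) + Eg[g + 1] * w


def _augmented_step_rates(gen: GeneratorSet, st: int, E_here: np.ndarray):
    """Anagenetic row and hidden-cladogenesis rates out of ``st``."""
    q_row = gen.Q[st]
    outs = gen.outcomes_of[st]
    h_left = gen.out_rate[outs] * E_here[gen.out_right[outs]]
    h_right = gen.out_rate[outs] * E_here[gen.out_left[outs]]
    return q_row, outs, h_left, h_right


def _augmented_forward(gen: GeneratorSet, grid, top_state: int,
                       age_top: float, age_bottom: float, rng):
    """One thinned forward path of the augmented process.

    Returns ``(events, end_state)``; hidden cladogenetic transitions occur
    at rate r_o * E_sibling(t), interpolated from the branch grid.
    """
    ages, Eg, bound = grid
    events: list[Event] = []
    a = age_top
    st = top_state
    while True:
        a = a - rng.exponential(1.0 / bound[st])
        if a <= age_bottom:
            return events, st
        E_here = _interp_E(ages, Eg, a)
        q_row, outs, h_left, h_right = _augmented_step_rates(gen, st, E_here)
        total = q_row.sum() + h_left.sum() + h_right.sum()
        if rng.random() * bound[st] >= total:
            continue  # thinned (virtual) event
        u = rng.random() * total
        if u < q_row.sum():
            j = int(np.searchsorted(np.cumsum(q_row), u))
            events.append(Event(
                age=a, kind=EventKind.ANAGENETIC,
                move_class=gen.q_move[(st, j)], from_state=st,
                to_states=(j,), state_changed=True))
            st = j
        else:
            u -= q_row.sum()
            hl = np.concatenate([h_left, h_right])
            oo = int(np.searchsorted(np.cumsum(hl), u))
            if oo < len(outs):
                o, j = outs[oo], int(gen.out_left[outs[oo]])
            else:
                o = outs[oo - len(outs)]
                j = int(gen.out_right[o])
            events.append(Event(
                age=a, kind=EventKind.CLADOGENETIC_HIDDEN,
                move_class=gen.out_class[o], from_state=st,
                to_states=(j,), state_changed=(j != st),
                extra=({"region": int(gen.out_region[o])}
                       if gen.out_region[o] >= 0 else {})))
            st = j


def sample_branch_path(
    gen: GeneratorSet,
    top_state: int,
    bottom_state: int,
    age_top: float,
    age_bottom: float,
    rng: np.random.Generator,
    grid_points: int = 100,
    max_tries: int = 10000,
    E_sol=None,
    sampling_fraction: float = 1.0,
) -> list[Event]:
    """Rejection-sample one branch history conditioned on both endpoints.

    Simulates the anagenetic process augmented with hidden cladogenetic
    transitions forward from the rootward end and rejects paths that miss
    ``bottom_state``.  Events come back rootward-to-tipward (decreasing
    age).
    """
    rates = _Rates(gen)
    if E_sol is None:
        E_sol = _solve_E(rates, sampling_fraction, age_top, 1e-8, 1e-10)
    grid = _branch_grid(rates, gen, E_sol, age_bottom, age_top, grid_points)
    for _ in range(max_tries):
        events, st = _augmented_forward(gen, grid, top_state, age_top,
                                        age_bottom, rng)
        if st == bottom_state:
            return events
    raise MappingError(
        f"branch rejection sampling failed after {max_tries} tries "
        "(acceptance below floor); review parameters or increase max_tries")


def stochastic_maps(
    tree,
    tips: dict[str, set[int]],
    gen: GeneratorSet,
    n_maps: int,
    seed: int,
    sampling_fraction: float = 1.0,
    root_weighting="fitzjohn",
    grid_points: int = 100,
    max_tries: int = 10000,
    k_segments: int = 100,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[MappedHistory]:
    """Draw replicate joint histories conditional on tips and parameters.

    Node states come from their exact joint conditional distribution
    (root-to-tip pass over stored per-branch partials and solution
    operators); branch interiors are filled by endpoint-conditioned
    rejection sampling including hidden cladogenetic events.  A single
    integer seed spawns one independent child stream per map.
    """
    pas = _likelihood_pass(tree, tips, gen, sampling_fraction, "ode",
                           rtol, atol, compute_K=True, k_segments=k_segments)
    ti, rates = pas.ti, pas.rates
    n = rates.n
    D = pas.D_root
    if isinstance(root_weighting, (int, np.integer)):
        w = np.zeros(n)
        w[int(root_weighting)] = 1.0
    elif root_weighting == "uniform":
        w = np.full(n, 1.0 / n)
    else:
        w = D / D.sum()
    root_post = _normalize(w * D)

    # per-branch grids shared by all maps
    grids = {}
    for c in range(1, ti.n_nodes):
        a0, a1 = ti.age[c], ti.age[ti.parent[c]]
        grids[c] = _branch_grid(rates, gen, pas.E_sol, a0, a1, grid_points)

    seeds = np.random.SeedSequence(seed).spawn(n_maps)
    maps = []
    for m in range(n_maps):
        rng = np.random.default_rng(seeds[m])
        maps.append(_sample_one_map(pas, gen, root_post, grids, rng,
                                    grid_points, max_tries, m))
    return maps


def _draw(rng, probs):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return int(rng.choice(len(p), p=p))


def _draw_daughters(gen: GeneratorSet, rng, i: int,
                    DL: np.ndarray, DR: np.ndarray):
    outs = gen.outcomes_of[i]
    if len(outs) == 0:
        raise MappingError(f"state {i} has no cladogenetic outcomes")
    wl = 0.5 * gen.out_rate[outs] * DL[gen.out_left[outs]] * DR[gen.out_right[outs]]
    wr = 0.5 * gen.out_rate[outs] * DL[gen.out_right[outs]] * DR[gen.out_left[outs]]
    weights = np.concatenate([wl, wr])
    if weights.sum() <= 0:
        raise MappingError("zero daughter-pair weight at node")
    pick = _draw(rng, weights)
    if pick < len(outs):
        o = outs[pick]
        j, k = int(gen.out_left[o]), int(gen.out_right[o])
    else:
        o = outs[pick - len(outs)]
        j, k = int(gen.out_right[o]), int(gen.out_left[o])
    return o, j, k


def _sample_one_map(pas: _Pass, gen: GeneratorSet, root_post, grids, rng,
                    grid_points, max_tries, map_index) -> MappedHistory:
    ti = pas.ti
    root_state = _draw(rng, root_post)
    branches: list[BranchHistory] = []

    def node_event(i_state: int, node: int, age: float):
        c1, c2 = ti.children[node]
        o, j, k = _draw_daughters(gen, rng, i_state, pas.D_top[c1],
                                  pas.D_top[c2])
        ev = Event(age=age, kind=EventKind.CLADOGENETIC_NODE,
                   move_class=gen.out_class[o], from_state=i_state,
                   to_states=(j, k),
                   state_changed=(j != i_state or k != i_state),
                   extra=({"region": int(gen.out_region[o])}
                          if gen.out_region[o] >= 0 else {}))
        return ev, {c1: j, c2: k}

    ev, assign = node_event(root_state, 0, ti.root_age)
    branches.append(BranchHistory(
        branch_index=0, parent_node=-1, child_node=0,
        start_age=ti.root_age, end_age=ti.root_age,
        start_state=root_state, end_state=root_state, events=[ev]))

    stack = list(assign.items())
    while stack:
        c, top_state = stack.pop()
        a0, a1 = ti.age[c], ti.age[ti.parent[c]]
        post_bottom = pas.K[c][top_state, :] * pas.D_bottom[c]
        if post_bottom.sum() <= 0:
            raise MappingError(
                f"no feasible bottom state on branch {c}; solution "
                "operator and data are incompatible")
        bottom_state = _draw(rng, post_bottom)
        path = _conditioned_path(pas, gen, grids[c], top_state, bottom_state,
                                 a1, a0, rng, max_tries)
        events = path
        if ti.children[c]:
            nev, nassign = node_event(bottom_state, c, a0)
            events = path + [nev]
            stack.extend(nassign.items())
        branches.append(BranchHistory(
            branch_index=c, parent_node=int(ti.parent[c]), child_node=c,
            start_age=a1, end_age=a0, start_state=top_state,
            end_state=bottom_state, events=events, label=ti.label[c]))
    branches.sort(key=lambda b: b.branch_index)
    return MappedHistory(branches=branches, extra={"map_index": map_index})


def _conditioned_path(pas, gen, grid, top_state, bottom_state,
                      age_top, age_bottom, rng, max_tries) -> list[Event]:
    """Endpoint-conditioned branch fill.

    Plain rejection sampling of the augmented process first (fast for
    typical branches); when the endpoint pair is too improbable for the
    try budget, falls back to uniformization of the same augmented
    process, which samples the conditioned path directly instead of
    erroring out on a legitimate but rare history.
    """
    for _ in range(max(200, max_tries // 50)):
        events, st = _augmented_forward(gen, grid, top_state, age_top,
                                        age_bottom, rng)
        if st == bottom_state:
            return events
    return _uniformized_path(gen, grid, top_state, bottom_state,
                             age_top, age_bottom, rng)


def _hidden_rate_matrix(gen: GeneratorSet, E_here: np.ndarray):
    """Hidden-cladogenesis rates H[a, j] and the self-rate vector H[a, a]."""
    n = gen.n_states
    H = np.zeros((n, n))
    np.add.at(H, (gen.out_parent, gen.out_left),
              gen.out_rate * E_here[gen.out_right])
    np.add.at(H, (gen.out_parent, gen.out_right),
              gen.out_rate * E_here[gen.out_left])
    h_self = H.diagonal().copy()
    np.fill_diagonal(H, 0.0)
    return H, h_self


def _typed_jump_event(gen: GeneratorSet, a: int, j: int, age: float,
                      E_here: np.ndarray, rng) -> Event:
    """Attribute a state jump a -> j to an anagenetic move or hidden event."""
    q = gen.Q[a, j]
    outs = gen.outcomes_of[a]
    hw = np.zeros(len(outs))
    hw += np.where(gen.out_left[outs] == j,
                   gen.out_rate[outs] * E_here[gen.out_right[outs]], 0.0)
    hw += np.where(gen.out_right[outs] == j,
                   gen.out_rate[outs] * E_here[gen.out_left[outs]], 0.0)
    total = q + hw.sum()
    if total <= 0 or rng.random() * total < q:
        return Event(age=age, kind=EventKind.ANAGENETIC,
                     move_class=gen.q_move[(a, j)], from_state=a,
                     to_states=(j,), state_changed=True)
    o = outs[_draw(rng, hw)]
    return Event(age=age, kind=EventKind.CLADOGENETIC_HIDDEN,
                 move_class=gen.out_class[o], from_state=a,
                 to_states=(j,), state_changed=(j != a),
                 extra=({"region": int(gen.out_region[o])}
                        if gen.out_region[o] >= 0 else {}))


def _self_hidden_event(gen: GeneratorSet, a: int, age: float,
                       E_here: np.ndarray, rng) -> Event:
    outs = gen.outcomes_of[a]
    hw = np.zeros(len(outs))
    hw += np.where(gen.out_left[outs] == a,
                   gen.out_rate[outs] * E_here[gen.out_right[outs]], 0.0)
    hw += np.where(gen.out_right[outs] == a,
                   gen.out_rate[outs] * E_here[gen.out_left[outs]], 0.0)
    o = outs[_draw(rng, hw)]
    return Event(age=age, kind=EventKind.CLADOGENETIC_HIDDEN,
                 move_class=gen.out_class[o], from_state=a,
                 to_states=(a,), state_changed=False,
                 extra=({"region": int(gen.out_region[o])}
                        if gen.out_region[o] >= 0 else {}))


def _uniformized_path(gen: GeneratorSet, grid, top_state, bottom_state,
                      age_top, age_bottom, rng,
                      n_segments: int = 20) -> list[Event]:
    """Direct endpoint-conditioned sampling by piecewise uniformization.

    The branch is split into segments with the augmented generator held
    constant per segment (E at the segment midpoint); segment-edge states
    are drawn from the exact conditional chain and each segment interior
    by uniformization of the constant-rate process.  Hidden cladogenetic
    self-events (a real speciation whose surviving daughter keeps the
    parent state) do not alter the path, so they are overlaid afterwards
    as a thinned Poisson process along the sampled trajectory.
    """
    ages_g, Eg, bound = grid
    n = gen.n_states
    length = age_top - age_bottom
    S = max(1, n_segments)
    edges = np.linspace(age_top, age_bottom, S + 1)  # descending
    A_list, P_list, hself_list, Emid_list = [], [], [], []
    for s in range(S):
        mid = 0.5 * (edges[s] + edges[s + 1])
        E_here = _interp_E(ages_g, Eg, mid)
        H, h_self = _hidden_rate_matrix(gen, E_here)
        A = gen.Q + H
        np.fill_diagonal(A, 0.0)
        np.fill_diagonal(A, -A.sum(axis=1))
        A_list.append(A)
        P_list.append(expm(A * (edges[s] - edges[s + 1])))
        hself_list.append(h_self)
        Emid_list.append(E_here)
    suffix = [None] * (S + 1)
    suffix[S] = np.eye(n)
    for s in range(S - 1, -1, -1):
        suffix[s] = P_list[s] @ suffix[s + 1]
    if suffix[0][top_state, bottom_state] <= 0:
        raise MappingError(
            "endpoint pair unreachable under the augmented process")
    # segment-edge states conditioned on both branch endpoints
    x = [top_state]
    for s in range(S):
        w = P_list[s][x[-1], :] * suffix[s + 1][:, bottom_state]
        x.append(_draw(rng, w))
    events: list[Event] = []
    for s in range(S):
        a_st, b_st = x[s], x[s + 1]
        A = A_list[s]
        dt = edges[s] - edges[s + 1]
        omega = float(-A.diagonal().min())
        if omega <= 0:
            continue
        R = np.eye(n) + A / omega
        # number of uniformized jumps given the endpoints
        Rpow = [np.eye(n)]
        pab = P_list[s][a_st, b_st]
        probs = []
        pois = math.exp(-omega * dt)
        cum = 0.0
        nj = 0
        while cum < 1.0 - 1e-10 and nj < 500:
            probs.append(pois * Rpow[-1][a_st, b_st] / pab)
            cum += probs[-1]
            Rpow.append(Rpow[-1] @ R)
            nj += 1
            pois *= omega * dt / nj
        njumps = _draw(rng, np.maximum(probs, 0.0))
        if njumps == 0:
            continue
        times = np.sort(rng.uniform(0.0, dt, size=njumps))[::-1]
        st = a_st
        for i in range(njumps):
            w = R[st, :] * Rpow[njumps - i - 1][:, b_st]
            nxt = _draw(rng, w)
            if nxt != st:
                age = edges[s] - (dt - times[i])
                E_here = _interp_E(ages_g, Eg, age)
                events.append(_typed_jump_event(gen, st, nxt, age, E_here,
                                                rng))
                st = nxt
        # virtual self-jumps of R carry no information and are dropped
    # overlay hidden self-speciations along the realized trajectory
    traj = _trajectory(events, top_state, age_top, age_bottom)
    self_events = []
    for (a_hi, a_lo, st) in traj:
        rate_bound = float(bound[st]) + 1e-12
        a = a_hi
        while True:
            a -= rng.exponential(1.0 / rate_bound)
            if a <= a_lo:
                break
            E_here = _interp_E(ages_g, Eg, a)
            outs = gen.outcomes_of[st]
            hw = (np.where(gen.out_left[outs] == st,
                           gen.out_rate[outs] * E_here[gen.out_right[outs]],
                           0.0)
                  + np.where(gen.out_right[outs] == st,
                             gen.out_rate[outs] * E_here[gen.out_left[outs]],
                             0.0))
            if rng.random() * rate_bound < hw.sum():
                self_events.append(
                    _self_hidden_event(gen, st, a, E_here, rng))
    events = sorted(events + self_events, key=lambda e: -e.age)
    return events


def _trajectory(events, top_state, age_top, age_bottom):
    """Constant-state stretches (older_age, younger_age, state)."""
    out = []
    a, st = age_top, top_state
    for ev in events:
        out.append((a, ev.age, st))
        a = ev.age
        st = ev.to_states[0]
    out.append((a, age_bottom, st))
    return out


# ---------------------------------------------------------------------------
# maximum-likelihood fitting

def fit_lambda_within(
    tree,
    tips: dict[str, set[int]],
    params: ClasseParameters,
    space: StateSpace,
    sampling_fraction: float | None = None,
    method: str = "grid",
    n_grid: int = 200,
    maxiter: int = 200,
    **loglik_kw,
):
    """Maximum-likelihood estimate of the per-region speciation rates.

    Optimizes ``lambda_within`` on the log scale with the remaining rates
    held at the values in ``params``.  Returns ``(fitted_params, result)``
    where ``result`` is the scipy optimization record.
    """
    nreg = space.regions.n
    rho = (params.sampling_fraction if sampling_fraction is None
           else sampling_fraction)
    ti = TreeIndex(tree) if isinstance(tree, dendropy.Tree) else tree
    x0 = np.log(np.maximum(params.lambda_within_per_region(nreg), 1e-4))

    def negloglik(x):
        p = ClasseParameters(
            lambda_within=tuple(np.exp(x)),
            lambda_between=params.lambda_between,
            dispersal=params.dispersal,
            biome_rate=params.biome_rate,
            extirpation=params.extirpation,
            sampling_fraction=rho,
        )
        gen = build_generators(p, space)
        try:
            return -classe_loglik(ti, tips, gen, rho, method=method,
                                  n_grid=n_grid, **loglik_kw)
        except (RuntimeError, FloatingPointError):
            return 1e10

    res = minimize(negloglik, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-3,
                            "fatol": 1e-4})
    fitted = ClasseParameters(
        lambda_within=tuple(np.exp(res.x)),
        lambda_between=params.lambda_between,
        dispersal=params.dispersal,
        biome_rate=params.biome_rate,
        extirpation=params.extirpation,
        sampling_fraction=rho,
    )
    return fitted, res
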