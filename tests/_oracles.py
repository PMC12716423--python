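"""Independent brute-force oracles for the likelihood machinery.

Everything here is written from the model definition directly, without
touching the package's solver path: a fixed-step RK4 integrator over
explicit outcome lists, a hand-rolled pruning pass, and a matrix-
exponential CTMC likelihood.  Used to pin down expected values in tests.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm


class ToyModel:
    """Explicit ClaSSE specification for the brute-force integrator.

    ``outcomes`` is a list of (parent, left, right, rate) unordered
    daughter pairs; ``Q`` anagenetic rates (diagonal ignored), ``mu``
    lineage extinction.
    """

    def __init__(self, Q, mu, outcomes, rho=1.0):
        self.Q = np.asarray(Q, dtype=float)
        np.fill_diagonal(self.Q, 0.0)
        self.mu = np.asarray(mu, dtype=float)
        self.outcomes = [(int(p), int(j), int(k), float(r))
                         for p, j, k, r in outcomes]
        self.rho = float(rho)
        self.n = self.Q.shape[0]
        self.lam_tot = np.zeros(self.n)
        for p, _, _, r in self.outcomes:
            self.lam_tot[p] += r
        self.loss = self.lam_tot + self.Q.sum(axis=1) + self.mu

    def derivs(self, E, D):
        dE = self.mu - self.loss * E + self.Q @ E
        dD = -self.loss * D + self.Q @ D
        for p, j, k, r in self.outcomes:
            dE[p] += r * E[j] * E[k]
            dD[p] += r * (D[j] * E[k] + D[k] * E[j])
        return dE, dD

    def node_combine(self, DL, DR):
        out = np.zeros(self.n)
        for p, j, k, r in self.outcomes:
            out[p] += 0.5 * r * (DL[j] * DR[k] + DL[k] * DR[j])
        return out


def rk4_branch(model: ToyModel, E0, D0, t0, t1, h=1e-3):
    """Fixed-step RK4 integration of the coupled E/D system."""
    n_steps = max(1, int(math.ceil((t1 - t0) / h)))
    dt = (t1 - t0) / n_steps
    E, D = np.array(E0, dtype=float), np.array(D0, dtype=float)

    def f(y):
        E_, D_ = y[: model.n], y[model.n:]
        dE, dD = model.derivs(E_, D_)
        return np.concatenate([dE, dD])

    y = np.concatenate([E, D])
    for _ in range(n_steps):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y[: model.n], y[model.n:]


def brute_force_loglik(model: ToyModel, topology, tip_states, h=1e-3,
                       root_weighting="fitzjohn",
                       condition_on_survival=False):
    """Pruning likelihood with RK4 branches.

    ``topology`` is a nested tuple tree: a leaf is ``(name, length)``, an
    internal node ``((childA, childB), length)``; the root length is
    ignored.  ``tip_states`` maps leaf name to a state index (or a set).
    Returns the log-likelihood.
    """
    logscale = [0.0]

    def age_of(node):
        kids, length = node
        if isinstance(kids, str):
            return 0.0
        return age_of(kids[0]) + kids[0][1]

    def post(node):
        kids, length = node
        if isinstance(kids, str):
            D = np.zeros(model.n)
            states = tip_states[kids]
            if isinstance(states, int):
                states = {states}
            for s in states:
                D[s] = model.rho
            E = np.full(model.n, 1.0 - model.rho)
            return 0.0, E, D
        aL, EL, DL = post(kids[0])
        aL_top = aL + kids[0][1]
        EL, DL = rk4_branch(model, EL, DL, aL, aL_top, h)
        aR, ER, DR = post(kids[1])
        aR_top = aR + kids[1][1]
        ER, DR = rk4_branch(model, ER, DR, aR, aR_top, h)
        if abs(aL_top - aR_top) > 1e-9:
            raise ValueError("non-ultrametric toy tree")
        D = model.node_combine(DL, DR)
        s = D.max()
        D = D / s
        logscale[0] += math.log(s)
        return aL_top, EL, D

    age, E_root, D_root = post(topology)
    if root_weighting == "uniform":
        w = np.full(model.n, 1.0 / model.n)
    else:
        w = D_root / D_root.sum()
    v = D_root.copy()
    if condition_on_survival:
        denom = model.lam_tot * (1.0 - E_root) ** 2
        ok = denom > 0
        v = np.divide(v, denom, out=np.zeros_like(v), where=ok)
    return math.log(float(w @ v)) + logscale[0]


def ctmc_loglik(Q, tree_topology, tip_states, root_weights=None):
    """Plain CTMC character likelihood by expm pruning (no diversification)."""
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    G = Q.copy()
    np.fill_diagonal(G, 0.0)
    np.fill_diagonal(G, -G.sum(axis=1))

    def post(node):
        kids, length = node
        if isinstance(kids, str):
            L = np.zeros(n)
            states = tip_states[kids]
            if isinstance(states, int):
                states = {states}
            for s in states:
                L[s] = 1.0
        else:
            L = post(kids[0]) * post(kids[1])
        if length > 0:
            L = expm(G * length) @ L
        return L

    L_root = post(tree_topology)
    if root_weights is None:
        root_weights = L_root / L_root.sum()
    return math.log(float(root_weights @ L_root))


def conditioned_ctmc_mean_changes(q: float, t: float, terms: int = 200) -> float:
    """E[#changes | X_0 = X_t] for the 2-state symmetric chain.

    Changes are Poisson(q t); the endpoint condition keeps even counts:
    E[N | N even] = x sinh(x) / cosh(x) with x = q t (independent series).
    """
    x = q * t
    num = 0.0
    den = 0.0
    term = 1.0  # x^n / n!
    for nn in range(terms):
        if nn % 2 == 0:
            num += nn * term
            den += term
        term *= x / (nn + 1)
    return num / den


def enumerate_paths_max_prob(nodes, edges, k):
    """Exhaustive max-product path probability between all node pairs.

    ``edges`` is a list of (i, j, cost); probability of a path is the
    product of exp(-k * cost) over its edges.  Brute force over simple
    paths; only for tiny graphs.
    """
    import itertools

    n = len(nodes)
    adj = {i: [] for i in nodes}
    for i, j, c in edges:
        p = math.exp(-k * c)
        adj[i].append((j, p))
        adj[j].append((i, p))
    best = {(i, i): 1.0 for i in nodes}

    def dfs(start, current, visited, prob):
        for nxt, p in adj[current]:
            if nxt in visited:
                continue
            np_ = prob * p
            key = (start, nxt)
            if np_ > best.get(key, 0.0):
                best[key] = np_
            dfs(start, nxt, visited | {nxt}, np_)

    for s in nodes:
        dfs(s, s, {s}, 1.0)
    return best


def brute_force_pixel_cost(resistance, start, goal, neighborhood=8):
    """Minimal accumulated cost between two pixels by exhaustive DFS.

    Step cost = mean endpoint resistance x step length (1 orthogonal,
    sqrt(2) diagonal).  Only for grids of a dozen pixels or so.
    """
    nrows, ncols = resistance.shape
    if neighborhood == 8:
        moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1),
                 (1, 0), (1, 1)]
    else:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    best = [math.inf]

    def dfs(pos, visited, cost):
        if cost >= best[0]:
            return
        if pos == goal:
            best[0] = cost
            return
        r, c = pos
        for dr, dc in moves:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrows and 0 <= nc < ncols):
                continue
            if (nr, nc) in visited or not np.isfinite(resistance[nr, nc]):
                continue
            step = math.sqrt(2) if dr and dc else 1.0
            w = 0.5 * (resistance[r, c] + resistance[nr, nc]) * step
            dfs((nr, nc), visited | {(nr, nc)}, cost + w)

    dfs(start, {start}, 0.0)
    return best[0]
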