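"""Arctic-alpine habitat networks and the probability of connectivity.

Works on gridded annual mean temperature (equal-area cells assumed).
Pixels whose temperature, rounded half-away-from-zero to whole degrees,
falls in the closed 0-6 degC window form the alpine biome.  Resistance to
movement is the distance of the rounded temperature from that window
(zero on alpine pixels; no-data pixels are impassable).  Alpine patches
(connected components) become network nodes; a least-cost path between
two patches becomes an edge whenever its accumulated cost is strictly
below a threshold (250 by default).  Movement probability decays
exponentially with cost, calibrated so that a cost distance of 150 maps
to probability 0.05, and the probability of connectivity statistic

    PC = sum_ij a_i a_j p*_ij / A^2

sums over ordered patch pairs (p*_ii = 1) with p*_ij the maximum-product
path probability through the retained network; A is the total alpine
area, so PC is the probability that two random alpine pixels are
interconnected.  Physical barriers (ice sheets, coastlines) are ignored
by design: resistance is purely thermal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "TemperatureGrid",
    "Patch",
    "PatchNetwork",
    "DEFAULT_COST_THRESHOLD",
    "DEFAULT_DECAY_K",
    "read_ascii_grid",
    "write_ascii_grid",
    "round_half_away",
    "classify_alpine",
    "label_patches",
    "resistance_surface",
    "patch_cost_distances",
    "build_network",
    "edge_probability",
    "probability_of_connectivity",
    "pc_time_series",
]

ALPINE_T_MIN = 0
ALPINE_T_MAX = 6
DEFAULT_COST_THRESHOLD = 250.0
#: decay constant: movement probability 0.05 at cost distance 150
DEFAULT_DECAY_K = math.log(20.0) / 150.0


@dataclass
class TemperatureGrid:
    """Annual mean temperature raster (degC); NaN marks no-data cells."""

    values: np.ndarray
    cell_size: float = 50.0      # km
    time_step: float | None = None  # Ma before present

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid must be a nonempty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)


def read_ascii_grid(path, time_step: float | None = None) -> TemperatureGrid:
    """Read an ESRI ASCII grid (ncols/nrows/.../NODATA_value header)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    vals = np.asarray(
        np.concatenate([np.asarray(r) for r in rows]), dtype=float)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    vals = vals.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals[vals == nodata] = np.nan
    cell = header.get("cellsize", 50.0)
    return TemperatureGrid(vals, cell_size=cell, time_step=time_step)


def write_ascii_grid(grid: TemperatureGrid, path,
                     nodata_value: float = -9999.0) -> None:
    vals = np.where(np.isnan(grid.values), nodata_value, grid.values)
    nrows, ncols = vals.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write("xllcorner 0\nyllcorner 0\n")
        fh.write(f"cellsize {grid.cell_size:g}\n")
        fh.write(f"NODATA_value {nodata_value:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")


def round_half_away(t: np.ndarray) -> np.ndarray:
    """Round to whole degrees, halves away from zero (6.5 -> 7, -0.5 -> -1)."""
    t = np.asarray(t, dtype=float)
    return np.where(t >= 0, np.floor(t + 0.5), np.ceil(t - 0.5))


def classify_alpine(grid: TemperatureGrid) -> np.ndarray:
    """Boolean alpine mask: rounded temperature within [0, 6] degC."""
    if grid.nodata_mask.all():
        raise ValueError("grid is entirely no-data")
    with np.errstate(invalid="ignore"):
        t = round_half_away(grid.values)
        mask = (t >= ALPINE_T_MIN) & (t <= ALPINE_T_MAX)
    mask &= ~grid.nodata_mask
    return mask


@dataclass
class Patch:
    """One alpine habitat patch: connected alpine pixels with an area."""

    id: int
    pixels: np.ndarray          # (k, 2) row/col indices
    area: float                 # km^2

    @property
    def n_cells(self) -> int:
        return self.pixels.shape[0]


def _structure(neighborhood: int) -> np.ndarray:
    if neighborhood == 8:
        return np.ones((3, 3), dtype=bool)
    if neighborhood == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    raise ValueError("neighborhood must be 4 or 8")


def label_patches(mask: np.ndarray, cell_size: float = 50.0,
                  neighborhood: int = 8) -> list[Patch]:
    """Connected components of the alpine mask, ids in scan order."""
    labels, n = ndimage.label(mask, structure=_structure(neighborhood))
    patches = []
    for i in range(1, n + 1):
        pix = np.argwhere(labels == i)
        patches.append(Patch(id=i - 1, pixels=pix,
                             area=float(pix.shape[0]) * cell_size ** 2))
    return patches


def resistance_surface(grid: TemperatureGrid) -> np.ndarray:
    """Per-pixel cost: distance of the rounded temperature from [0, 6].

    Zero on alpine pixels, ``T - 6`` above the window, ``-T`` below it;
    no-data pixels are impassable (infinite cost).
    """
    t = round_half_away(grid.values)
    cost = np.maximum(0.0, np.maximum(t - ALPINE_T_MAX, ALPINE_T_MIN - t))
    cost[grid.nodata_mask] = np.inf
    return cost


def _pixel_graph(resistance: np.ndarray, neighborhood: int = 8):
    """Sparse lattice graph; step cost = mean endpoint resistance x length."""
    nrows, ncols = resistance.shape
    passable = np.isfinite(resistance)
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        offsets += [(1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))]
    rows_l, cols_l, data = [], [], []
    for dr, dc, step in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a, b = idx[r0, c0].ravel(), idx[r1, c1].ravel()
        ok = passable[r0, c0].ravel() & passable[r1, c1].ravel()
        w = 0.5 * (resistance[r0, c0].ravel()
                   + resistance[r1, c1].ravel()) * step
        rows_l.append(a[ok])
        cols_l.append(b[ok])
        data.append(w[ok])
    n = nrows * ncols
    return coo_matrix(
        (np.concatenate(data),
         (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n, n)).tocsr()


def patch_cost_distances(patches: list[Patch], resistance: np.ndarray,
                         neighborhood: int = 8) -> np.ndarray:
    """Minimal accumulated cost between every patch pair.

    Multi-source Dijkstra over the pixel lattice; moving between adjacent
    pixels costs the mean of their resistances times the step length (1
    orthogonal, sqrt(2) diagonal, in cell units).  Within a patch all
    pixels are mutually reachable at zero cost, so one source pixel per
    patch suffices.  Unreachable pairs are infinite.
    """
    npat = len(patches)
    dist = np.zeros((npat, npat))
    if npat <= 1:
        return dist
    graph = _pixel_graph(resistance, neighborhood)
    ncols = resistance.shape[1]
    sources = [p.pixels[0][0] * ncols + p.pixels[0][1] for p in patches]
    allpix = dijkstra(graph, directed=False, indices=sources)
    for i in range(npat):
        for j in range(i + 1, npat):
            pj = patches[j].pixels
            d = allpix[i, pj[:, 0] * ncols + pj[:, 1]].min()
            dist[i, j] = dist[j, i] = d
    return dist


@dataclass
class PatchNetwork:
    """Patch graph for one time step: nodes with areas, least-cost edges."""

    patches: list[Patch]
    edges: list[tuple[int, int, float]]
    cost_threshold: float = DEFAULT_COST_THRESHOLD
    decay_k: float = DEFAULT_DECAY_K
    time_step: float | None = None

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for p in self.patches:
            g.add_node(p.id, area=p.area)
        for i, j, cost in self.edges:
            g.add_edge(i, j, cost=cost)
        return g

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["patch_i", "patch_j", "cost"])


def build_network(patches: list[Patch], distances: np.ndarray,
                  cost_threshold: float = DEFAULT_COST_THRESHOLD,
                  decay_k: float = DEFAULT_DECAY_K,
                  time_step: float | None = None) -> PatchNetwork:
    """Retain links whose least-cost distance is strictly below threshold."""
    edges = []
    for i in range(len(patches)):
        for j in range(i + 1, len(patches)):
            if distances[i, j] < cost_threshold:
                edges.append((i, j, float(distances[i, j])))
    return PatchNetwork(patches=patches, edges=edges,
                        cost_threshold=cost_threshold, decay_k=decay_k,
                        time_step=time_step)


def edge_probability(cost, k: float = DEFAULT_DECAY_K):
    """Movement probability exp(-k cost); k calibrated to 0.05 at 150."""
    cost = np.asarray(cost, dtype=float)
    if (cost < 0).any():
        raise ValueError("cost must be nonnegative")
    return np.exp(-k * cost)


def probability_of_connectivity(network: PatchNetwork,
                                denominator: str = "alpine",
                                landscape_area: float | None = None) -> float:
    """PC over the retained patch network.

    ``p*_ij`` is the maximum product of edge probabilities over network
    paths, equal to ``exp(-k d_ij)`` with ``d_ij`` the shortest-path cost
    over retained edges (self pairs count 1, unreachable pairs 0).  The
    default denominator is total alpine area squared ("two random alpine
    pixels"); ``denominator='landscape'`` uses a supplied total landscape
    area instead, as in the classical index.
    """
    if not network.patches:
        raise ValueError("network has no patches")
    areas = np.array([p.area for p in network.patches])
    if denominator == "alpine":
        A = areas.sum()
    elif denominator == "landscape":
        if not landscape_area or landscape_area <= 0:
            raise ValueError("landscape denominator needs landscape_area")
        A = float(landscape_area)
    else:
        raise ValueError("denominator must be 'alpine' or 'landscape'")
    if A <= 0:
        raise ValueError("zero alpine area")
    g = network.graph()
    total = 0.0
    spl = dict(nx.all_pairs_dijkstra_path_length(g, weight="cost"))
    for i, pi in enumerate(network.patches):
        lengths = spl.get(pi.id, {pi.id: 0.0})
        for j, pj in enumerate(network.patches):
            if pj.id in lengths:
                p = math.exp(-network.decay_k * lengths[pj.id])
                total += areas[i] * areas[j] * p
    return total / (A * A)


def pc_time_series(grids: list[TemperatureGrid],
                   cost_threshold: float = DEFAULT_COST_THRESHOLD,
                   decay_k: float = DEFAULT_DECAY_K,
                   neighborhood: int = 8) -> pd.DataFrame:
    """Apply the full chain per time step.

    Returns a table (time, n_patches, alpine_area, n_edges, pc); steps
    with no alpine pixels get NaN PC and are flagged undefined.
    """
    rows = []
    for step, grid in enumerate(grids):
        t = grid.time_step if grid.time_step is not None else step
        mask = classify_alpine(grid)
        if not mask.any():
            rows.append((t, 0, 0.0, 0, float("nan"), False))
            continue
        patches = label_patches(mask, grid.cell_size, neighborhood)
        res = resistance_surface(grid)
        dist = patch_cost_distances(patches, res, neighborhood)
        net = build_network(patches, dist, cost_threshold, decay_k, t)
        pc = probability_of_connectivity(net)
        rows.append((t, len(patches), sum(p.area for p in patches),
                     len(net.edges), pc, True))
    return pd.DataFrame(rows, columns=[
        "time", "n_patches", "alpine_area", "n_edges", "pc", "defined"])
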