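"""Synthetic inputs: paleo-temperature grids, clades, occurrence tables.

These generators stand in for the study-scale inputs (paleoclimate
reconstructions, time-calibrated phylogenies, cleaned occurrence records)
so that every stage of the pipeline can be exercised with known truth.

* Temperature grids combine a latitudinal gradient, Gaussian-profile
  mountain massifs cooled by a lapse rate, a per-time-step global offset
  (a monotone cooling trend), and a seeded smooth Gaussian noise field.
* Clade scenarios are named parameter presets for the compound-state
  simulator that emphasize one assembly regime each: a within-region
  "speciation engine", biome-boundary recruitment, and a dispersal
  "crossroads".
* Occurrence tables carry per-record elevations and local treeline
  elevations; a record is alpine when it lies at or above the treeline
  (the treeline is the alpine biome's lower boundary, so ties count as
  alpine), and species are classified alpine / both / nonalpine from the
  fraction of alpine records with inclusive 25% and 5% thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .classe import ClasseParameters, build_generators, simulate_clade
from .connectivity import TemperatureGrid
from .state_space import Biome, RegionSet, StateSpace, build_state_space

__all__ = [
    "GridScenario",
    "make_paleo_grids",
    "CladeScenario",
    "SimulatedClade",
    "CLADE_PRESETS",
    "make_scenario_clade",
    "scenario_space",
    "make_occurrence_table",
    "classify_by_treeline",
    "classify_species_biome",
]


# ---------------------------------------------------------------------------
# paleoclimate grids

@dataclass
class GridScenario:
    """Recipe for a sequence of cooling paleo-temperature grids.

    ``offsets`` holds one global temperature offset (degC) per time step;
    a monotonically decreasing sequence emulates long-term cooling.  Rows
    run south (warm, row 0) to north; ``gradient`` is degC lost per cell
    row.  Massifs are ``(row, col, radius_cells, peak_km)`` Gaussian
    bumps cooled by ``lapse_rate`` degC per km of elevation.
    """

    shape: tuple[int, int] = (60, 80)
    cell_size: float = 50.0
    base_temp: float = 24.0
    gradient: float = 0.5
    massifs: tuple[tuple[float, float, float, float], ...] = (
        (15.0, 20.0, 6.0, 4.5),
        (22.0, 55.0, 8.0, 3.5),
        (40.0, 35.0, 5.0, 2.5),
    )
    lapse_rate: float = 6.5
    offsets: tuple[float, ...] = (0.0, -2.0, -4.0, -6.0, -8.0)
    noise_amplitude: float = 0.5
    noise_corr_length: float = 3.0
    seed: int = 0

    def elevation(self) -> np.ndarray:
        nrows, ncols = self.shape
        rr, cc = np.mgrid[0:nrows, 0:ncols]
        elev = np.zeros(self.shape)
        for row, col, radius, peak in self.massifs:
            d2 = (rr - row) ** 2 + (cc - col) ** 2
            elev += peak * np.exp(-d2 / radius**2)
        return elev


def make_paleo_grids(scenario: GridScenario) -> list[TemperatureGrid]:
    """Temperature per step: base - gradient*row - lapse*elev + offset + noise.

    Noise is an independent seeded smooth field per time step (white noise
    convolved with a Gaussian kernel of the stated correlation length,
    rescaled to the given amplitude as a standard deviation); with zero
    amplitude the construction is exactly monotone in the offsets.
    """
    nrows, ncols = scenario.shape
    if nrows < 1 or ncols < 1:
        raise ValueError("degenerate grid extent")
    rows = np.arange(nrows)[:, None]
    elev = scenario.elevation()
    base = scenario.base_temp - scenario.gradient * rows \
        - scenario.lapse_rate * elev
    streams = np.random.SeedSequence(scenario.seed).spawn(len(scenario.offsets))
    grids = []
    for t, off in enumerate(scenario.offsets):
        vals = base + off
        if scenario.noise_amplitude > 0:
            rng = np.random.default_rng(streams[t])
            white = rng.standard_normal(scenario.shape)
            smooth = ndimage.gaussian_filter(white, scenario.noise_corr_length)
            sd = smooth.std()
            if sd > 0:
                vals = vals + scenario.noise_amplitude * smooth / sd
        grids.append(TemperatureGrid(vals, cell_size=scenario.cell_size,
                                     time_step=float(t)))
    return grids


# ---------------------------------------------------------------------------
# clade scenarios

#: three-region chain used by the presets: a focal region flanked by a
#: corridor region connecting to the far region (0 - 1 - 2)
_SCENARIO_REGIONS = RegionSet.from_pairs(
    ("Focal", "Corridor", "Far"),
    [("Focal", "Corridor"), ("Corridor", "Far")],
)


def scenario_space(n_regions: int = 3, max_range_size: int | None = None) -> StateSpace:
    """State space used by the clade presets (chain adjacency)."""
    if n_regions == 3:
        regions = _SCENARIO_REGIONS
    else:
        labels = [f"R{i}" for i in range(n_regions)]
        regions = RegionSet.from_pairs(
            labels, [(labels[i], labels[i + 1]) for i in range(n_regions - 1)])
    return build_state_space(
        regions, max_range_size if max_range_size is not None else n_regions)


@dataclass(frozen=True)
class _Preset:
    params: ClasseParameters
    root_regions: tuple[str, ...]
    root_biome: Biome
    max_age: float


CLADE_PRESETS: dict[str, _Preset] = {
    # in situ speciation dominates assembly of the focal region
    "SPECIATION_ENGINE": _Preset(
        params=ClasseParameters(
            lambda_within=(0.5, 0.08, 0.08), lambda_between=0.02,
            dispersal=0.04, biome_rate=0.04, extirpation=0.03),
        root_regions=("Focal",), root_biome=Biome.ALPINE, max_age=12.0),
    # recruitment across the biome boundary dominates
    "RECRUITMENT": _Preset(
        params=ClasseParameters(
            lambda_within=0.15, lambda_between=0.02,
            dispersal=0.06, biome_rate=0.5, extirpation=0.03),
        root_regions=("Focal",), root_biome=Biome.NONALPINE, max_age=15.0),
    # colonization into the focal region dominates
    "CROSSROADS": _Preset(
        params=ClasseParameters(
            lambda_within=0.15, lambda_between=0.02,
            dispersal=0.5, biome_rate=0.05, extirpation=0.03),
        root_regions=("Corridor",), root_biome=Biome.ALPINE, max_age=20.0),
}


@dataclass
class CladeScenario:
    preset: str
    n_regions: int = 3
    seed: int = 0
    max_age: float | None = None
    sampling_fraction: float = 1.0


@dataclass
class SimulatedClade:
    """Simulator outputs plus the generating configuration."""

    tree: object
    tips: dict
    truth: object
    params: ClasseParameters
    space: StateSpace
    root_state: int
    max_age: float
    seed_used: int


def make_scenario_clade(scenario: CladeScenario,
                        max_attempts: int = 50) -> SimulatedClade:
    """Simulate one clade under a named preset.

    Deterministic under ``scenario.seed``; if the clade goes extinct the
    seed is re-derived deterministically (seed + 7919 * attempt) until a
    surviving clade is produced.
    """
    if scenario.preset not in CLADE_PRESETS:
        raise KeyError(f"unknown preset {scenario.preset!r}; "
                       f"choose from {sorted(CLADE_PRESETS)}")
    preset = CLADE_PRESETS[scenario.preset]
    space = scenario_space(scenario.n_regions)
    gen = build_generators(preset.params, space)
    root = space.index_of(space.state(preset.root_regions, preset.root_biome))
    max_age = scenario.max_age if scenario.max_age is not None else preset.max_age
    last_err: Exception | None = None
    from .classe import CladeExtinctError  # local to avoid cycle at import

    for attempt in range(max_attempts):
        seed = int(scenario.seed + 7919 * attempt) % (2**31 - 1)
        try:
            tree, truth, tips = simulate_clade(
                gen, root, max_age, seed,
                sampling_fraction=scenario.sampling_fraction)
            return SimulatedClade(tree=tree, tips=tips, truth=truth,
                                  params=preset.params, space=space,
                                  root_state=root, max_age=max_age,
                                  seed_used=seed)
        except CladeExtinctError as err:
            last_err = err
    raise RuntimeError(
        f"no surviving clade in {max_attempts} attempts") from last_err


# ---------------------------------------------------------------------------
# occurrence tables and the biome classifier

ALPINE_THRESHOLD = 0.25
BOTH_THRESHOLD = 0.05


def make_occurrence_table(
    alpine_fractions: Sequence[float],
    n_records: int = 40,
    seed: int = 0,
    treeline_mean: float = 2200.0,
    treeline_sd: float = 150.0,
) -> pd.DataFrame:
    """Occurrence records with known per-species alpine fractions.

    One species per entry of ``alpine_fractions``; each gets ``n_records``
    records whose elevations are placed above or below the local treeline
    so that the realized alpine fraction matches the requested one exactly
    (``round(f * n_records)`` alpine records).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for si, f in enumerate(alpine_fractions):
        n_alp = int(round(f * n_records))
        for k in range(n_records):
            treeline = rng.normal(treeline_mean, treeline_sd)
            if k < n_alp:
                elev = treeline + rng.uniform(0.0, 600.0)
            else:
                elev = treeline - rng.uniform(1.0, 1200.0)
            rows.append((f"sp{si}", f"site{si}_{k}", elev, treeline))
    df = pd.DataFrame(rows, columns=["species", "site", "elevation",
                                     "treeline_elevation"])
    df["alpine_flag"] = classify_by_treeline(df)
    return df


def classify_by_treeline(occ: pd.DataFrame) -> pd.Series:
    """Flag records at or above the local treeline as alpine.

    The treeline is the lower spatial boundary of the alpine biome, so a
    record exactly on the treeline counts as alpine.
    """
    if occ["treeline_elevation"].isna().any():
        raise ValueError("missing treeline elevation")
    return occ["elevation"] >= occ["treeline_elevation"]


def classify_species_biome(
    occ: pd.DataFrame,
    alpine_threshold: float = ALPINE_THRESHOLD,
    both_threshold: float = BOTH_THRESHOLD,
) -> dict[str, Biome]:
    """Classify species from the fraction of alpine records.

    Thresholds are the minimum fractions *required* for a class, hence
    inclusive: f >= 25% -> alpine, 5% <= f < 25% -> both, f < 5% ->
    nonalpine.
    """
    if "alpine_flag" not in occ.columns:
        occ = occ.assign(alpine_flag=classify_by_treeline(occ))
    counts = occ.groupby("species")["alpine_flag"].agg(["mean", "count"])
    if (counts["count"] == 0).any():
        raise ValueError("species with no records")
    out: dict[str, Biome] = {}
    for sp, f in counts["mean"].items():
        if f >= alpine_threshold:
            out[sp] = Biome.ALPINE
        elif f >= both_threshold:
            out[sp] = Biome.BOTH
        else:
            out[sp] = Biome.NONALPINE
    return out
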