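# alpassembly

Tools for asking how regional alpine floras were assembled: did the
resident species arise by **in situ speciation** within the region, bud
off widespread ancestors (**subset speciation**), **colonize** from other
regions, or recruit locally across the treeline (**niche expansion**)?
And when the climate cooled, how connected did arctic-alpine habitats
become?

The package is aimed at phylogenetic biogeographers. It implements:

* a **compound-state ClaSSE model** in which a lineage's character is a
  geographic range (a connected set of regions under a user-supplied
  adjacency, capped in size) joined with a biome-occupancy flag
  (nonalpine `a`, alpine `A`, or both `Aa`; the pure states are two
  anagenetic steps apart via `Aa`). Per-region speciation rates λ_r, one
  between-region (vicariant) rate, a dispersal rate for range expansion,
  one biome-transition rate, per-region extirpation rates and a clade
  sampling fraction ρ parameterize the process. The likelihood integrates
  the standard coupled system

      dE_i/dt = μ_i − (Λ_i + Q_i + μ_i)E_i + Σ_j Q_ij E_j + Σ_(jk) λ_i,jk E_j E_k
      dD_i/dt = −(Λ_i + Q_i + μ_i)D_i + Σ_j Q_ij D_j + Σ_(jk) λ_i,jk (D_j E_k + D_k E_j)

  branch by branch, so unobserved speciation, extinction and incomplete
  sampling are accounted for;
* a **forward simulator** and **stochastic character mapping** (exact
  joint node-state draws; branch interiors by rejection sampling of the
  hidden-cladogenesis-augmented process, with a uniformization fallback
  for rare endpoint pairs), producing replicate joint histories in a
  versioned, extensible **JSON event format**;
* **assembly-rate accounting**: events classified per region into in situ
  speciation, subset speciation, colonization (with source attribution),
  niche expansion/contraction and local extinction; rolling per-capita
  rates λ(t) = s(t)/n(t−1) in 1-Ma windows, median and 25–75% quantile
  envelopes across replicate histories with leading-zero masking,
  region-pair interchange matrices, and assembly-proportion summaries;
* **habitat connectivity**: alpine pixels are those with annual mean
  temperature rounding into 0–6 °C; resistance is the thermal distance
  from that window; alpine patches become nodes of a graph whose edges
  are least-cost paths with cost < 250, and overall connectedness is the
  probability of connectivity PC = Σ a_i a_j p*_ij / A² with movement
  probability exp(−k·cost) calibrated to 0.05 at cost 150;
* **synthetic data generators** for cooling paleo-temperature grid
  sequences, clades simulated under named assembly regimes, and
  occurrence tables for the treeline/threshold biome classifier
  (record alpine iff at or above the local treeline; species alpine at
  ≥ 25% alpine records, "both" at ≥ 5%).

## A worked example

Simulate a clade under a "speciation engine" regime (a fast-speciating
focal region flanked by two quieter ones), reconstruct replicate
histories by stochastic mapping, and summarize how the focal region's
alpine flora was assembled:

```python
import numpy as np
from alpassembly import (build_state_space, RegionSet, Biome,
                         ClasseParameters, build_generators,
                         simulate_clade, classe_loglik, stochastic_maps,
                         classify_events)
from alpassembly.rates import assembly_proportions, compute_rate_series

regions = RegionSet.from_pairs(
    ["Focal", "Corridor", "Far"],
    [("Focal", "Corridor"), ("Corridor", "Far")])
space = build_state_space(regions, max_range_size=3)
print(f"{space.n_states} compound states")

params = ClasseParameters(
    lambda_within=(0.5, 0.08, 0.08), lambda_between=0.02,
    dispersal=0.1, biome_rate=0.1, extirpation=0.03)
gen = build_generators(params, space)
root = space.index_of(space.state(["Focal"], Biome.ALPINE))

tree, truth, tips = simulate_clade(gen, root, max_age=12.0, seed=2)
print(f"{len(tips)} sampled tips")

ll = classe_loglik(tree, tips, gen, params.sampling_fraction)
print(f"log-likelihood at the generating rates: {ll:.2f}")

maps = stochastic_maps(tree, tips, gen, n_maps=20, seed=1)
events = [classify_events(m, space) for m in maps]
props = assembly_proportions(events, region=0)
for proc, share in props["shares"].items():
    print(f"{proc:>16s} share: {share:.2f}")
print(f"in situ within cladogenesis: "
      f"{props['in_situ_within_cladogenesis']:.2f}")

rs = compute_rate_series(events, region=0,
                         process="IN_SITU_SPECIATION", max_age=12.0)
print("masked median per-capita rate, oldest -> present:")
print(np.round(rs.masked_envelopes["median"], 3))
```

Output:

```
18 compound states
154 sampled tips
log-likelihood at the generating rates: -447.11
    cladogenesis share: 0.87
    colonization share: 0.00
 niche_expansion share: 0.13
in situ within cladogenesis: 0.74
masked median per-capita rate, oldest -> present:
[0.    0.    0.    0.    0.    0.    1.    0.312 0.297 0.556 0.426 0.511]
```

Read: across 20 replicate reconstructions, 87% of the focal region's
assembly events were cladogenetic (74% of those in situ — new alpine
species from alpine ancestors in the same region), 13% were local
recruitment across the biome boundary, and colonization played no role —
as expected under this generating regime. The rate series is the median
per-capita in situ speciation rate per 1-Ma window (events per lineage
per Ma); windows older than the last empty window are masked to zero.

Connectivity works the same way from temperature grids:

```python
from alpassembly.synthetic import GridScenario, make_paleo_grids
from alpassembly.connectivity import pc_time_series

grids = make_paleo_grids(GridScenario(seed=3))   # a cooling sequence
print(pc_time_series(grids)[["time", "n_patches", "n_edges", "pc"]])
```

A command-line layer mirrors the library (`alpassembly simulate | loglik
| map | rates | interchange | proportions | connectivity | synth ...`);
see `alpassembly --help`.

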