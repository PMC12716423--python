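# Methods

## The joint range–biome diversification model

A lineage's character is a compound state `(range, biome)`: a nonempty set
of biogeographic regions together with a biome-occupancy flag taking three
values — nonalpine only (`a`), alpine only (`A`), or both (`Aa`). Ranges
are constrained to induce a connected subgraph of a user-supplied region
adjacency matrix and to contain at most `max_range_size` regions (default
4). Biome occupancy is uniform across the occupied regions: a biome shift
applies to the whole range at once. The two pure biome states are never
one anagenetic step apart; a lineage must pass through `Aa`. Range moves
and biome moves never combine in a single step. With six regions the
state count depends on the adjacency matrix and the range cap, both of
which are configurable (the bundled Northern-Hemisphere default gives
111 states with a cap of 4).

Evolution follows a cladogenetic state-dependent speciation–extinction
(ClaSSE) process. Rate parameters (all in events · lineage⁻¹ · Ma⁻¹):

| parameter | meaning | sharing |
|---|---|---|
| `lambda_within[r]` | within-region speciation rate of region r | per region |
| `lambda_between` | between-region (vicariant) speciation rate | one value |
| `dispersal` | range-expansion rate per occupied adjacent source region | one value |
| `biome_rate` | rate of each allowed biome shift | one value |
| `extirpation[r]` | loss of region r from a range; whole-lineage death for endemics | per region or shared |
| `sampling_fraction` | probability an extant species is sampled (ρ ∈ (0, 1]) | per clade |

Cladogenetic outcomes are unordered daughter pairs. Within-region
speciation in region r keeps the parent state on one daughter and buds a
single-region daughter `({r}, b′)`; from a pure-biome parent the bud
inherits the parent biome, from an `Aa` parent the bud may take any of the
three biome values (this is the only reading under which an alpine
endemic can bud off a widespread mixed-biome ancestor — subset
speciation). The region's rate `lambda_within[r]` is split equally over
that region's distinct outcomes, and `lambda_between` equally over the
valid connected bipartitions of the range. Lineage extinction (`mu`)
applies only to single-region states; wider ranges shrink by extirpation
of one region at a time.

## Likelihood

The standard coupled ClaSSE system is integrated tipward→rootward per
branch. With unordered outcomes `o = (j, k)` of rate `r_o`,

    dE_i/dt = mu_i − (Λ_i + Q_i + mu_i) E_i + Σ_j Q_ij E_j + Σ_o r_o E_j E_k
    dD_i/dt = −(Λ_i + Q_i + mu_i) D_i + Σ_j Q_ij D_j + Σ_o r_o (D_j E_k + D_k E_j)

with tip conditions `D_i(0) = ρ·1[i compatible]`, `E_i(0) = 1 − ρ`, node
combination `D_i = Σ_o r_o (D^L_j D^R_k + D^L_k D^R_j)/2`, per-branch
log-rescaling of D to avoid underflow, and root handling by
likelihood-proportional (FitzJohn-style) state weights by default
(uniform and fixed-state options are exposed). Conditioning on survival
of both root daughters divides per-state by `Λ_i (1 − E_i)²` and is on by
default but off in closed-form checks. Trees must be binary and
ultrametric (time-calibrated, tips at the present).

Two numerical paths:

* `method="ode"` (default): one adaptive stiff/non-stiff (LSODA) solve
  per branch, relative tolerance 1e−8, absolute 1e−10. Used wherever
  high precision matters; it matches an independent fixed-step RK4
  integrator to ~1e−11 relative on a four-tip oracle problem.
* `method="grid"`: E is solved once globally (it is autonomous and
  independent of D); D is propagated by products of per-interval matrix
  exponentials of the linear operator `B(t) = Q + H(t) − diag(Λ + Q + mu)`
  with E frozen at interval midpoints, on a global age grid (`n_grid`
  intervals, default 200; second-order accurate). Roughly an order of
  magnitude faster, used inside optimization loops. At `n_grid = 200` on
  a ~600-branch tree the discretization error is a few 1e−3 log units —
  negligible against the likelihood curvature at that data size.

`fit_lambda_within` maximizes the likelihood over the per-region
speciation rates on the log scale (Nelder–Mead) with the remaining rates
held fixed; it exists to validate parameter recovery, not to replace full
Bayesian inference over all rates.

## Stochastic mapping

Joint histories conditional on the tips are drawn in two stages:

1. **Node states** come from their exact joint conditional: the root from
   `π_i D_i`, daughter-pair assignments at each node proportionally to
   `r_o D^L_j D^R_k`, and the state at the tipward end of each branch from
   `K[top, ·] · D_bottom`, where `K` is the solution operator of the
   linear D system along that branch (a matrix ODE solved by the same
   midpoint-exponential rule, 100 segments per branch).
2. **Branch interiors** are filled conditionally on both endpoints by
   rejection sampling of the anagenetic process augmented with
   hidden-cladogenesis transitions: state `a → b` at time-varying rate
   `Σ_o r_o E_sibling(t)` — a real speciation whose other daughter leaves
   no sampled descendants. E(t) is interpolated from a 100-point grid per
   branch and proposals are thinned against a per-state bound.

Rejection sampling is fast for typical branches but its acceptance can be
arbitrarily small for legitimate rare endpoint pairs (e.g. three required
moves on a short branch). Rather than failing at an acceptance floor, the
sampler falls back to direct endpoint-conditioned sampling by piecewise
uniformization of the same augmented process (20 segments per branch,
generator frozen at segment midpoints): segment-edge states are drawn
from the exact conditional chain, segment interiors by conditioned
uniformization, and hidden self-speciations (daughter keeps the parent
state) — which do not affect the path — are overlaid afterwards as a
thinned Poisson process along the realized trajectory. Both routes sample
the same law up to the shared piecewise treatment of E(t); the
uniformization route is validated against the analytic conditional
expectation `x·tanh(x)` for a symmetric two-state chain.

Sampled node-state frequencies are checked against marginal ancestral
probabilities computed by an independent uppass through the stored
solution operators. A single integer seed spawns one child stream per
map, so map `m` of `n` is reproducible in isolation.

## Histories and event accounting

Histories serialize to a versioned JSON format
(`src/alpassembly/schema/history.schema.json`): per branch, the states at
both ends plus a chained event list; events are anagenetic moves,
cladogenetic node events (ordered daughter pair) or hidden cladogenetic
events, each flagged for whether the state changed. Unknown fields
round-trip untouched. The root, having no parent branch, is stored as a
zero-length branch record carrying the root's node event. Simulator
lineage deaths are serialized as anagenetic `EXTINCTION` events with an
unchanged state so that full (unpruned) truth histories fit the same
schema.

`classify_events` maps raw state changes to assembly processes relative
to a focal biome (alpine by default):

* **in situ speciation** — cladogenetic event whose parent is exactly
  `({r}, A)`; counted once per event.
* **subset speciation** — a daughter `({r}, A)` from a parent strictly
  containing region r's alpine biome. This unifies the biome-subset
  (parent `Aa`) and range-subset (parent with a wider range, including
  vicariant splits) cases; a `detail` field distinguishes them.
* **colonization** — range expansion adding r while the biome includes
  alpine; sources are the occupied regions with equal weights
  (an adjacent-only attribution is available).
* **niche expansion / contraction** — `a → Aa` / `Aa → a`, counted once
  per occupied region (a per-lineage count can be recovered through the
  recorded branch coordinates).
* **local extinction** — contraction dropping r, or endemic death, while
  occupying alpine.

On simulator truth the classifier reproduces the simulator's own online
tally exactly; the two accountings are independent code paths.

## Rate series

Events are binned into 1-Ma windows labeled by the younger edge: an event
of age a goes to bin `ceil(a) − 1`, and an event exactly on an edge goes
to the younger bin. The regional lineage count n(t) is the running
balance of in situ + subset + niche expansion + colonization − local
extinction at the end of each window (floored at zero with a warning);
per-capita rates are `λ(t) = s(t)/n(t−1)`, defined as 0 when the lagged
count is 0, which suppresses pre-origin noise consistently with the
masking rule. Quantile envelopes (median, 25–75%) across replicates use
the linear-interpolation quantile definition, stated because replicate
counts are small in tests; masking zeroes every value older than the last
zero-valued window, independently per quantile trajectory. Interchange
matrices sum weighted colonizations into j attributed to i over whole
windows in a period and take the median across replicates; migration
balances are emitted in both weighted and unit-count conventions.

Two bookkeeping caveats, deliberate and documented rather than patched:
the balance formula does not subtract niche contraction (an option adds
it), and a vicariant split books a subset speciation in each daughter
region without a compensating loss for the disappearing widespread
parent. The simulator-census identity (balance at the present equals the
extant alpine lineage count) therefore holds exactly only for histories
without vicariance or mixed-biome budding, and that is the regime the
census test uses; in general the event set is richer than the printed
balance.

## Habitat connectivity

Temperatures are rounded to whole degrees half-away-from-zero; alpine
pixels are those with rounded temperature in the closed window 0–6 °C.
Grids are assumed equal-area (the reprojection to an equal-area grid is a
preprocessing contract, not part of this package); no-data cells are
impassable. Resistance is the distance of the rounded temperature from
the window (`max(0, T − 6, −T)`), so alpine pixels cost nothing.
Patches are 8-connected components (4-connectivity available), and the
step cost between adjacent pixels is the mean of their resistances times
the step length (1 orthogonal, √2 diagonal, in cell units) — a symmetric,
additive rule that is zero inside patches, chosen because the reference
GIS tool's exact accumulation rule is not published. Patch-to-patch
least-cost distances come from lattice Dijkstra (one source pixel per
patch suffices since intra-patch movement is free) and are validated
against exhaustive path enumeration on small grids. Edges are retained
when the least-cost distance is **strictly below** the threshold (default
250); no planar pruning is applied. Movement probability decays as
`exp(−k·cost)` with `k = ln 20/150`, i.e. 0.05 at a cost distance of 150,
and

    PC = Σ_i Σ_j a_i a_j p*_ij / A²,

summed over ordered patch pairs including self pairs (`p*_ii = 1`), with
`p*_ij` the maximum-product path probability over retained edges and A
the total alpine area — PC is then the probability that two random alpine
pixels are interconnected. The classical total-landscape denominator is
available as an option. Ice sheets, coastlines and sea-level barriers are
ignored by design: resistance is purely thermal.

## Synthetic data

* **Paleo-temperature grids**: base temperature minus a latitudinal
  gradient, minus lapse-rate cooling (6.5 °C/km) over Gaussian-profile
  massifs, plus a per-step global offset (monotone for cooling scenarios)
  and a seeded smooth noise field (white noise convolved with a Gaussian
  kernel, default amplitude 0.5 °C, correlation length 3 cells, an
  independent draw per time step). Alpine area grows monotonically under
  zero-noise cooling as long as no pixel exits the window through the
  cold edge; offsets in the bundled scenarios respect that. The grids do
  not emulate continents, ice sheets, orbital variability or the spatial
  covariance of real paleoclimate reconstructions, so connectivity tests
  validate the machinery, not any real-world PC value.
* **Clade presets** (three chained regions Focal–Corridor–Far):
  `SPECIATION_ENGINE` (within-region rate 0.5 in the focal region vs 0.08
  elsewhere, root an alpine focal endemic, 12 Ma), `RECRUITMENT` (biome
  rate 0.5, nonalpine root, 15 Ma) and `CROSSROADS` (dispersal 0.5, root
  alpine in the corridor region, 20 Ma). Background rates (dispersal
  0.04–0.06, extirpation 0.03, vicariance 0.02) are set so clades of tens
  to a few hundred tips arise in a realistic 12–20 Ma window. Presets are
  simulated forward, so their truth tallies are exact ground truth for
  the accounting layer; they do not emulate incomplete sampling,
  phylogenetic uncertainty or among-clade rate variation.
* **Occurrence tables**: records carry elevations and local treeline
  elevations; a record at or above the treeline is alpine (the treeline
  is the alpine biome's lower boundary, so ties count alpine). Species
  are classified from their alpine-record fraction f with inclusive
  thresholds: f ≥ 25% alpine, 5% ≤ f < 25% both, f < 5% nonalpine.
  The generator realizes requested fractions exactly; it does not emulate
  spatial sampling bias or coordinate error.

## Problem sizes and reproducibility

Validation uses a three-state, four-tip oracle problem for the likelihood
(fixed-step RK4, h = 5e−4, as the independent integrator), 2000 replicate
maps for calibration checks, and ten simulated clades of 300–1200 sampled
tips (three regions, 18 compound states) for parameter recovery, fitted
with the grid likelihood (`n_grid = 120`). These sizes keep the whole
validation suite at a few minutes on one core while leaving Monte-Carlo
error well below the tested tolerances. All stochastic components take a
single integer seed; generators, the simulator and the mapper are
bit-reproducible given that seed.

## Known limitations

* Full Bayesian inference (MCMC over all rates) is out of scope; the
  fitting helper covers the speciation rates only.
* The augmented-process branch fill (both rejection and uniformization)
  treats E(t) as piecewise interpolated on the branch grid; endpoint and
  node draws are exact up to the ODE/propagator tolerances.
* The grid likelihood assumes branch lengths are large relative to the
  grid step for its speed advantage; for very small trees the ODE path is
  both faster to set up and more accurate.
* Trees must be strictly binary and ultrametric; serially-sampled or
  fossil tips are not supported.
* PC treats patches as points connected by least-cost paths; within-patch
  cost structure and multiple parallel corridors between the same patch
  pair beyond the best one are ignored, as in the source index.
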