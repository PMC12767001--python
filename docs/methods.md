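# Methods

## Model

`aggsim` implements a minimal stochastic model of cellular protein
aggregation on a fixed 2D arrangement of cell centroids. Each cell is a
two-state unit — healthy or in a runaway aggregation state ("aggregated") —
and the switch is irreversible: there is no recovered state and no cell
death, mirroring SI-type spatial epidemic models on a point cloud. Two
channels trigger the switch:

* **cell-autonomous triggering** at rate `k_a` (per unit time): a
  spontaneous, nucleation-like event, independent of all other cells;
* **cell-to-cell triggering** at rate `k_s` with coupling length `σ` (µm):
  an induced, seeding-like event whose strength decays with the distance to
  each aggregated cell.

In a discrete step of length `Δt` a healthy cell `i` switches with
probability

    p_i = v_i · (1 − exp(−(k_a·Δt + λ_i)))

where `v_i ∈ [0, 1]` is a per-cell vulnerability multiplying the combined
trigger probability and `λ_i` is the *aggregation pressure*, the expected
number of cell-to-cell trigger events on cell `i` during the step. For the
default Gaussian kernel

    λ_i = k_s·Δt / (2π σ² ρ_c) · Σ_j exp(−d_ij² / 2σ²) · x_j ,

with `x_j = 1` for aggregated cells, `d_ij` the (minimum-image, under
periodic boundaries) pairwise distance, and `ρ_c = n/A` the overall cell
density.

**Why the `1/ρ_c` factor.** The kernel value summed over the cells of a
uniform arrangement is ≈ `ρ_c`, so dividing by it makes `λ` a pure event
count: a single aggregated cell exerts a total pressure of `k_s` per unit
time summed over all other cells, independent of how the field is
discretized into cells. Two consequences anchor the model's analysis and
would not hold without this normalization:

* in the well-mixed limit the aggregated fraction obeys
  `df/dt = k_a(1−f) + k_s·f(1−f)` exactly, so the two channels balance at
  the **switch fraction** `f_switch = k_a/k_s` (e.g. 0.001 at the
  representative ratio `k_s/k_a = 1000`);
* trajectories show the characteristic two-phase shape — a slow
  cell-autonomous phase followed by a much faster cell-to-cell phase once
  `f` passes `f_switch`.

Only the ratio `k_s/k_a` and `σ` shape patterns as a function of the
fraction aggregated; the absolute rate scale sets the (arbitrary) time
unit. Rescaling `(k_a, k_s) → (c·k_a, c·k_s)` reproduces the identical
realization with times divided by `c` (tested exactly).

### Coupling kernels

All kernels integrate to 1 over the plane so `k_s` keeps its meaning, and
the alternatives are matched to the Gaussian by second moment
(`E[d²] = 2σ²`) so regime comparisons happen at equal effective range:

| kernel | form | matching |
| --- | --- | --- |
| gaussian | `exp(−d²/2σ²) / 2πσ²` | — |
| exponential | `exp(−d/ℓ) / 2πℓ²` | `ℓ = σ/√3` |
| uniform_disc | `1{d ≤ R} / πR²` | `R = 2σ` |

The regime signatures (random-like vs clustered NND/RDF) are unchanged
across kernel forms at matched moments (tested).

### Time stepping

`Δt` is chosen adaptively and never grows:

* the maximum per-step hazard `k_a·Δt + λ_i` is capped at 0.01, so
  single-event-per-step discretization bias is below 1% (halving a fixed
  `Δt` changes mean trajectories by less than Monte-Carlo error; tested);
* the initial `Δt` is set so that ≈2 cell-autonomous events are expected in
  the first step (`Δt₀ = 2/(n·k_a)`). Without this, at high `k_s/k_a` the
  entire cell-autonomous phase would collapse into a single step and the
  two-phase trajectory would be unresolvable.

Vulnerability multiplies the *combined* probability (a single trigger
channel per step). Composing the two channels multiplicatively instead,
`(1−p_a)(1−p_s)`, differs at O(p²) ≤ 1e-4 under the hazard cap.

The engine keeps per-cell kernel sums incrementally: each newly aggregated
cell adds its exact (untruncated) kernel contribution to all cells in one
vectorized minimum-image pass, O(n) per aggregation event. A full-scale run
(10 002 cells to 20% aggregated) takes ~1 s on one CPU core.

## Synthetic arrangements

The generator emulates the cellular geometry of a cortical slice: `n` cells
in a square periodic box, x uniform, and a denser horizontal band across
the middle third of the y-range at 0.8× the spacing of the outer sections
(mimicking a cortical layer). Region densities follow the Poisson relation
`D = 1/(2·spacing)²` (the mean nearest-neighbour distance of a 2D Poisson
process of density `D` is `1/(2√D)`), and both region spacings are scaled
jointly so the density-weighted **overall** mean NND equals the target
(default 27.3 µm; defaults: 10 002 cells, band factor 0.8, band extent
1/3). The measured mean NND of the default arrangement is within a fraction
of a percent of the target.

What the generator does *not* emulate: real grey/white-matter boundaries,
cortical layering beyond a single band, anisotropy, vascular holes, or
segmentation noise. Tests passing on these arrangements demonstrate the
correctness of model and statistics, not that real tissue satisfies the
model's assumptions. Imported centroid tables (any segmentation pipeline's
export) are analysed with open boundaries instead of periodic ones.

## Spatial summaries

* **NND** — exact nearest-neighbour distances (KD-tree, minimum-image under
  periodic boundaries). Analytic limits: random (cell-autonomous)
  aggregation follows `2πrD·e^{−πr²D}` with `D` the aggregate density;
  direct-neighbour coupling follows the same law with the all-cell density
  `D_c`. Histogram bin width 10 µm (sub-cell-spacing at 27 µm).
* **Normalized RDF** — `g(r) = ⟨dn_r/(2πr·dr)⟩` over aggregated reference
  cells, with annulus width `dr = 50 µm` and `r_max = 2 mm` (clipped to
  half the shorter box side); `g_norm = g_agg/g_nuc` is the local fraction
  of cells aggregated at distance `r` (1 where fully aggregated, the
  overall fraction for a random pattern; NaN where `g_nuc = 0`). Periodic
  boxes need no edge correction; open slices drop reference cells within
  `r_max` of the boundary.
* **Rolling density** — counts per 100 µm × 100 µm grid cell divided by the
  window area, then averaged over the 7×7 surrounding cells (edge cells
  average over their in-bounds neighbours only).
* **Density segmentation** — a Gaussian is least-squares fitted to the
  histogram (Freedman–Diaconis bins) of rolling nucleus densities; grid
  cells below `µ−2σ` are background and excluded everywhere downstream; the
  rest split into low/mid/high at `µ∓σ/2`.
* **APN** — aggregates-per-nucleus, the ratio of the two rolling densities;
  `apn_ratio` = mean APN(high)/mean APN(low). Proportional grids (the
  cell-autonomous signature) give APN ≡ const and ratio 1; spatial coupling
  raises the ratio above 1. Class comparisons across simulation repeats use
  a two-tailed independent-samples t-test. The APN histogram uses 50
  uniform bins over [0, max observed APN], normalized to sum 1.
* **Cross-type NND** — mean distance from each aggregated cell of type A to
  the nearest aggregated B, against the Poisson baseline `1/(2√D_B)`.

On the banded synthetic arrangements the density histogram is bimodal; the
single-Gaussian fit locks onto the dominant (outer-region) mode, so the
"high" class captures the dense band and the "low" class the sparse
regions — exactly the contrast the APN diagnostic needs.

## Inference

Grid search over `k_s/k_a ∈ {0.001, 0.01, …, 1e5}` × `σ ∈ {50, 100, 200,
400, 600, 800} µm` (defaults), 10 repeats per point. Because post-mortem
data is an endpoint, simulations are compared to data at **equal fraction
aggregated** (first crossing), never equal time, with constant
vulnerability 1. The error is the mean bin-by-bin squared difference of the
chosen readout (APN histogram by default; NND, normalized RDF and 2D APN
images available); the best fit is the grid argmin, ties resolved toward
the smaller ratio, then the smaller σ (most parsimonious coupling).
`f_switch = 1/best_ratio` is attached to every fit.

The NND readout yields a lower bound on σ: the smallest grid σ whose
per-repeat errors are compatible with the σ-minimum (one-sided
Mann–Whitney test at α = 0.05).

Known identifiability limits, both documented and tested qualitatively:

* **σ–vulnerability degeneracy** — strongly varying vulnerability with a
  short coupling radius mimics constant vulnerability with a longer one, so
  under the constant-vulnerability fitting assumption `best_sigma` is an
  upper bound (a caveat flag on every `FitResult`).
* **σ–ratio trade-off at large σ** — when σ is a substantial fraction of
  the field, few clusters form, realization variance of the summaries is
  high, and the mean-squared-error surface flattens along a (ratio, σ)
  valley. Self-consistency recovery experiments therefore use a short-σ
  truth (σ = 100 µm on a ~3 mm field), where recovery is reliable
  (≥8/10 fits at 3 000 cells, 5 repeats, coarse 3×3 grid).

## Interventions

Scenarios scale `k_a`, `k_s` or all `v_i` (clipped to [0, 1]) from a
common partially aggregated initial state (default 1.8% aggregated). The
baseline defines `T_end` by first reaching the endpoint fraction; every
other scenario runs for exactly that simulated time, with checkpoints at
0%, 50%, 71% and 100% of the interval. Each scenario draws a fresh child
seed from the master seed, so scenarios are comparable but not artificially
coupled. Above `f_switch`, halving `k_s` (or `v`) clearly slows
progression while halving `k_a` leaves it essentially unchanged — the
model's central therapeutic prediction.

## Numerical choices and degenerate inputs

* Trigger draws are made in fixed cell-index order from one seeded
  generator per trajectory; identical seeds reproduce identical
  trajectories bit-for-bit.
* Zero rates with no seed cells, or all-zero vulnerability, raise a
  non-progress error rather than looping forever (step cap 1e6).
* Near-constant density grids make the Gaussian fit meaningless and raise
  a fit-failure error advising manual thresholds.
* `g_norm` is NaN where the nucleus RDF is zero; NaN bins are excluded from
  readout errors on both sides.
* Coincident points are legal everywhere; a point never counts itself as
  its own neighbour (self-pairs at distance 0 are excluded from RDF counts
  and `exclude_self` NND queries).

## Problem sizes used in the shipped checks

Full scale (10 002 cells) for generator calibration, the APN regime
discrimination (10 repeats per condition) and the analytic-NND comparison;
3 000 cells for parameter recovery (5 repeats per grid point, 3×3 grid,
10 replicate fits) and the intervention ordering (10 matched seeds);
2 000 cells and 2–3 repeats for the remaining inference unit tests. These
sizes keep the whole suite at a few minutes while leaving every statistical
margin wide.
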