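# Methods

This note documents the model, the numerical choices behind each
metric, and the places where the design was genuinely open.

## Landscape generation

Fractal surfaces are synthesised spectrally: complex Gaussian noise on
the 2-D frequency grid is scaled by `f^-(H+1)` (power spectrum
`f^-(2H+2)`, the fractional-Brownian-surface form), inverse-FFT'd, and
the real part kept. The zero-frequency amplitude is set to 0, so
surfaces have mean ≈ 0; only value *ranks* matter downstream. `H` must
lie in (0, 1]; higher `H` gives smoother, more clumped fields (verified
as increasing Moran's I in the tests). All simulations here use
`H = 0.9`, characteristic of heavily aggregated forest cover.

Deforestation gradients threshold one fixed surface by descending rank:
a cell is forest at cover `c` iff its rank falls in the top
`floor(c·N)` cells, ties broken by row-major position. This construction
was chosen over iterative edge erosion because it guarantees, exactly
and reproducibly, the two properties that matter for the experiments —
nested forest sets along the gradient (sequential loss over one base
landscape) and realised cover equal to nominal cover up to integer
rounding. Under high `H` the removed cells concentrate at patch edges,
so patch shape is approximately preserved along the gradient. A
`min_cover` floor (default 0) is available for emulating generators
that leave residual habitat at the nominal 0% level; the defaults keep
0% meaning zero forest, which is why our 0%-cover treatment has no
patches (and its class metrics are all 0 by convention) rather than the
~0.8% residual a stochastic eroder can leave.

The world never wraps; the grid records this and the simulator reflects
agents off the boundary.

## Class metrics

Patches are maximal connected components of forest cells,
8-connectivity by default (the common raster convention; 4-connectivity
is available). Perimeter counts cell edges adjacent to non-forest or to
the grid boundary. SHAPE = 0.25·p/√a, which scores 1 for any square
raster patch and grows with irregularity. AREA metrics are reported in
hectares; the area-weighted variants weight each patch by its share of
total forest area. CONNECT counts patch pairs whose minimum
centre-to-centre cell distance is ≤ the functional threshold (default
50 m, a bee gap-crossing distance), as a percentage of all `n(n−1)/2`
pairs; a single patch (or none) scores 0. Cell-centre distance is used
as the tractable raster proxy for edge-to-edge distance, and the
threshold comparison is inclusive (≤); both choices affect only
borderline pairs and are configurable in the tests' oracle comparison.

## The foraging model

All individuals of a species start at its nest cell centre with
independent uniform headings. Each tick a living bee:

1. turns by a wrapped-normal angle (σ = 40°). The empirically derived
   bumblebee turning distribution used by earlier bee-scouting models is
   not published as a table, so a symmetric unimodal default with
   moderate directional persistence was adopted; it is a parameter, not
   a commitment.
2. steps by `max(Normal(2, 0.5), 0.1)` cell lengths. Only the mean
   (2 cells = 20 m) is empirically anchored; the spread and floor keep
   steps positive without materially changing mean displacement.
3. reflects off world edges (specular; heading mirrored), pays energy
   equal to the distance flown, and records a visit if the cell under
   its new position — cell `(⌊y⌋, ⌊x⌋)`, half-open boundaries — hosts a
   flower in its diet. Repeat landings on later ticks count again; the
   nest cell at tick 0 does not count.

A bee whose drawn step exceeds its remaining energy still completes the
step, then dies; this avoids biasing final step lengths. Lifetimes are
therefore `energy / E[step]` ticks in expectation (≈ 25 / 50 / 99 for
the three groups), so all flights complete far inside the 150-tick
horizon. Flower detection is contact-only (no sensing radius), and
return flights, colony dynamics, flower depletion and non-energetic
mortality are out of scope.

Specialists nest only in forest: on a landscape with no forest cell the
species is marked absent for the run (logged), rather than an error —
the 0%-cover treatments depend on this. Flower placement samples
distinct cells of the species' guild without replacement across
species; when a guild's habitat is too small the species receives what
remains, again logged.

## Network metrics

Nestedness is NODF: for every pair of rows (and of columns), the
percentage of the sparser line's links shared with the strictly denser
line, averaged over all pairs; computed on the matrix pruned to species
with ≥ 1 interaction and validated against a brute-force implementation
of the published formula. Matrices with fewer than two active rows or
columns return NaN and are dropped listwise in the regressions.

H₂′ standardises the two-dimensional Shannon entropy `H₂ = −Σ p·ln p`
between the extreme entropies attainable by *integer* matrices with the
observed marginal totals: `H₂′ = (H₂max − H₂)/(H₂max − H₂min)`, clamped
to [0, 1]. The extremes are found heuristically — largest-remainder
rounding of the independence table (for the maximum) and greedy mass
concentration (for the minimum), each refined by steepest-ascent
transfers along marginal-preserving 4-cycles (unit transfers for the
maximum; unit and full transfers for the minimum). Marginals are sorted
canonically first, which makes the result exactly invariant to row and
column permutations. The heuristic reproduces exhaustive-enumeration
extremes on all 3×3 marginal configurations with totals ≤ 6 to 1e−9.
Note that integer-constrained H₂′ is *not* exactly invariant to scaling
all counts by a constant — the attainable extremes sharpen as the total
grows — so only approximate scale invariance is asserted.

Connectance supports two denominators: the full configured matrix
(20 × 20 by default) and the active (pruned) matrix, the convention of
the standard R tooling for field data. The experiment pipeline records
both (`connectance_full`, `connectance`), and the analysis layer uses
the active convention: with a fixed simulated community the full-matrix
variant conflates link loss with species loss, whereas the active
variant is the quantity field studies report and respond to. Network
size counts active species of both guilds; asymmetry is
`(plants − bees)/(plants + bees)`.

## Experiments and analysis

The default design is 11 cover levels (0–100% in steps of 10) × 10
replicates = 110 runs. Each replicate draws one surface from seed
`SeedSequence([base_seed, replicate])` and thresholds it at all levels;
simulations use `SeedSequence([base_seed, replicate, level_index])`.
Diets are allocated once per design (from the base seed), and the
sensitivity driver re-runs the identical landscapes under freshly
seeded diet allocations. Results tables are sorted by (level,
replicate); content is order-independent.

The analysis fits 30 single-predictor GLMs — 5 network responses × 6
landscape predictors, identity-link Gaussian except log-link Poisson
for the count-valued network size — and the 6 × 6 Spearman matrix of
landscape metrics (average ranks for ties, t-approximation p-values).
Multivariable models are deliberately out of scope.

## What the synthetic data does and does not emulate

The generator reproduces the *statistical* conditions of the study —
clumped fractal habitat, sequential loss, constant community size and
flower density across the gradient — not any real landscape. Species
richness does not respond to habitat amount (only behaviour and
placement do), flower resources never deplete, and bee density is
constant by construction; passing tests therefore demonstrate the
internal logic of the mechanism (specialist loss drives network change
along deforestation gradients) and not calibration to any field system.
Emergent trends at full scale — H₂′ increasing and active-matrix
connectance decreasing with forest cover — arise from specialist
presence/absence and guild-limited flower placement, and are asserted
directionally (sign and significance), never by magnitude, since
magnitudes depend on unpublished movement parameters.

## Problem sizes and determinism

The full default experiment (110 runs × ≤ 150 ticks × 200 agents) takes
a few seconds on one CPU; the test suite re-uses one session-scoped
full experiment for its structural checks. Every public entry point is
a pure function of (configuration, seed); derived seeds stay below
2³¹.
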