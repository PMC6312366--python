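# pollinet

Agent-based simulation of bee foraging and plant–pollinator network
assembly over gradients of forest loss and fragmentation.

Plant–pollinator networks observed in the field are shaped both by real
ecological mechanisms and by incomplete sampling, which makes the
mechanisms behind network structure hard to isolate. `pollinet` provides
a virtual alternative: an individual-based model in which every
interaction is recorded perfectly, so that the response of network
structure to landscape change can be studied with sampling error
eliminated by construction. It is aimed at landscape and pollination
ecologists who want to run in-silico deforestation experiments, and at
modellers extending the bee community or movement rules.

## The model

- **World.** A 100 × 100 binary raster (forest / open vegetation) at
  10 m resolution — a 1 km² landscape. Synthetic landscapes are fractal
  surfaces (Hurst exponent *H* = 0.9, strongly clumped) thresholded by
  descending value rank at a series of forest-cover levels, so habitat
  loss is *sequential*: the forest at 30% cover is an exact subset of
  the forest at 70% cover.
- **Bees.** 20 species × 10 individuals in three functional groups:
  specialists (diet of 1 flower species, flight energy 50, nest in
  forest only; 9 species), generalists (4 / 100 / anywhere; 8 species)
  and super-generalists (8 / 200 / anywhere; 3 species). Diets are drawn
  at random from the flower community.
- **Flowers.** 20 species × 20 cells; half restricted to forest, half to
  open vegetation.
- **Movement.** A correlated random walk: per tick, a wrapped-normal
  turning angle (σ = 40°) and a truncated-normal step (mean 2 cells =
  20 m). Energy decreases by the distance flown (1 unit / cell); a bee
  landing on a cell that hosts a flower in its diet records one visit.
  Runs last at most 150 ticks; every flight ends well before that.
- **Output.** The summed bee-species × flower-species visit matrix — a
  pollination network — plus per-agent diagnostics.

Landscapes are scored with six class metrics (PLAND; AREA_MN/AREA_AM in
ha; SHAPE_MN/SHAPE_AM with SHAPE = 0.25·p/√a; CONNECT at a 50 m
functional distance), networks with five descriptors (connectance, NODF
nestedness, H₂′ complementary specialization, network size, web
asymmetry), and the experiment layer fits single-predictor GLMs
(Gaussian; Poisson for network size) of each network metric on each
landscape metric, plus Spearman correlations among the landscape
metrics.

## Worked example

```python
from pollinet import default_community, generate_surface, make_gradient, run_simulation
from pollinet.netmetrics import compute_metrics

grid = make_gradient(generate_surface(0.9, seed=5), [0.5]).grids[0]
result = run_simulation(grid, default_community(seed=1), seed=42)
m = compute_metrics(result.visits)
print(result.all_dead_tick, int(result.visits.counts.sum()), round(m.h2, 3))
```

prints `103 96 0.526`: all 200 bees exhausted their energy by tick 103,
recording 96 flower visits; the resulting network has an H₂′
specialization of 0.526 (0 = as generalized as the marginal totals
allow, 1 = perfectly reciprocal specialists). The scripts in
`examples/` walk through landscape generation and metrics, a single
simulation, and a reduced experiment with the GLM analysis.

The same pipeline is available from the shell:

```sh
pollinet landscape --hurst 0.9 --seed 5 --levels 0,10,20,30,40,50,60,70,80,90,100 --out maps/
pollinet simulate --map maps/landscape_cover050.asc --seed 7 --out visits.csv
pollinet netmetrics --in visits.csv
pollinet reproduce --out study/ --seed 5     # the full 110-run study
```

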