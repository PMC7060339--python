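# gardenflow

Circuit-theory analysis of **socio-ecological connectivity** across urban
community-garden networks, packaged as a reusable, tested pipeline that runs
end-to-end on seeded synthetic city landscapes.

Community gardens act simultaneously as ecological habitat patches and as
social hubs. Treating each garden as a node in an electrical network laid
over the city, the package asks how strongly the biophysical landscape
(land cover) and the social landscape (neighbourhood sociodemographics and
amenities) let ecosystem-service flows move between gardens — and where
gardens cluster into hotspots or sit isolated in coldspots. It is aimed at
landscape/urban ecologists and planners who want a desk-scale, fully
reproducible implementation of this workflow without any proprietary GIS or
external data downloads.

## The model

1. **Resistance surfaces.** A classified land-cover raster (canopy,
   grass/shrub, bare soil, water, buildings, roads/rail, other paved) is
   mapped to a biophysical resistance grid on a 1–180 scale (canopy 1,
   buildings 180; water removed from the circuit). The social surface is
   built from census-block-group covariates: pairs with Spearman
   |ρ| > 0.60 are screened, garden presence/absence is fit by logistic
   regression on standardized covariates over **every** covariate subset
   (an all-subsets dredge), models are averaged within the smallest set
   with cumulative Akaike weight Σω ≥ 0.97, and variables with importance
   weight 1.00 are retained. Each selected variable is split into tertiles
   scored 10/20/30 (direction set by the sign of its averaged coefficient),
   so six variables sum to a 60–180 base comparable to the biophysical
   scale. Amenity buffers (schools 500 m, parks 250 m, …) reduce resistance
   by 10% each, stacking multiplicatively; a 1 km edge-replicated buffer
   around the city limits edge effects.

2. **Current flow.** Valid cells become vertices of a lattice circuit with
   edge conductance g = 2/(r_i + r_j). For each garden pair, one ampere is
   injected and the graph-Laplacian system solved (sparse LU, or
   preconditioned CG for very large grids); per-cell current density
   ½·Σ|g·Δv| predicts net random-walker movement, and v_s − v_t is the
   pair's effective resistance. Densities summed over up to 500 pairs per
   surface map corridors ("pinch points") and diffuse "sheet flow".

3. **Comparison.** At uniform random points, each layer is min–max
   normalized to [0, 1] and summed to a combined score on [0, 2]
   (square-root transformed for its zero inflation); the slope of
   log-biophysical on log-social connectivity against the null line m = 1
   says which layer dominates.

4. **Hotspots.** Garden counts on a 500 m fishnet are tested with the
   Getis-Ord Gi\* statistic (binary 500 m distance-band weights, self
   included); z > +1 SD marks hotspots, z < −1 SD coldspots, and inverse
   distance weighting interpolates the z-surface.

The synthetic-city generator produces every input with known ground truth —
including garden presence planted through a logistic model with recorded
coefficients — so the whole chain (screening → dredge → averaging →
selection → scoring) can be validated by recovery tests.

## Worked example

```python
from gardenflow.scenario import ScenarioConfig
from gardenflow.pipeline import AnalysisConfig, run_scenario

scenario = ScenarioConfig(grid_shape=(100, 100), n_blockgroups=120,
                          n_gardens=10, seed=42)
analysis = AnalysisConfig(boundary_buffer_m=300.0, n_sample_points=5000)
manifest = run_scenario(scenario, analysis, "out/")

c = manifest.counts
print(f"selected variables: {c['selected_variables']}")
print(f"median social connectivity:      {c['summary']['median_social']:.3f}")
print(f"median biophysical connectivity: {c['summary']['median_biophysical']:.3f}")
print(f"median total connectivity:       {c['summary']['median_total']:.3f}")
print(f"log-log slope vs m=1: {c['slope']:.3f} ({c['slope_vs_null']})")
print(f"hot cells: {c['n_hot_cells']}, cold cells: {c['n_cold_cells']}")
```

prints

```
selected variables: ['avg_household_size', 'median_age', 'prop_black', 'prop_renters', 'prop_vacant']
median social connectivity:      0.022
median biophysical connectivity: 0.019
median total connectivity:       0.051
log-log slope vs m=1: 0.881 (social-dominant)
hot cells: 1, cold cells: 1
```

At this modest block-group count no covariate sits in *every*
confidence-set model, so the pipeline falls back to the best-AIC model's
five covariates, recorded in the manifest (strict importance-1.0 selection
recovers all six planted covariates reliably at n ≈ 2000); the
medians are on the normalized [0, 1] (layers) and [0, 2] (total) scales; a
slope below 1 means the social layer contributes relatively more
connectivity than the biophysical layer in this scenario; and the clustered
default garden pattern produces one Gi\* hotspot cell. The same run is
available from a shell via `gardenflow run-all --outdir out/ --seed 42`
(see `gardenflow --help` for per-stage subcommands), and every output file
is listed with a SHA-256 digest in `out/manifest.json` — rerunning with the
same config reproduces all of them byte-for-byte.

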