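# Methods

This note documents the models, parameter choices, numerical details and
known limitations of gardenflow. It describes what the code computes; every
empirical figure mentioned here is produced by the test suite or by
`scripts/acceptance.py`.

## Scope and assumptions

The package analyses connectivity of a network of community-garden nodes
over two resistance landscapes — biophysical (land cover) and social
(block-group sociodemographics plus amenity buffers) — using electrical
circuit theory, then compares, combines, and spatially characterises the
two connectivity layers. All analysis is on planar, square-celled, north-up
rasters in metric map units; gardens are points (centroids), with no
intra-garden habitat structure. Movement is isotropic and undirected: the
circuit model predicts expected net traversal of random walkers, not routed
or goal-directed movement.

## Synthetic city scenarios

Real inputs for this kind of study (classified aerial land cover, census
block-group tables, stakeholder garden registries) are large and partly
proprietary, so the package ships a generator that emulates their
*statistical structure* with recorded ground truth.

- **Land cover.** A Gaussian-smoothed noise field (σ = 4 cells) is sliced
  at the quantiles of configurable mixing proportions (water 3%, canopy
  18%, grass/shrub 27%, bare soil 5%, other paved 27%, buildings 20% of
  non-road cells), giving contiguous patches in the neutral-landscape
  tradition; a road lattice is overlaid every 25 cells. The default extent
  is 200×200 cells at 10 m — desk-scale rather than the 3 m full-city
  rasters of production studies — and fully configurable.
- **Block groups.** The extent is tiled by exactly `n_blockgroups`
  rectangles (row bands with varying column counts). Six named covariates
  (average household size, median age, proportion Black, proportion
  Hispanic, proportion renters, proportion vacant) are drawn from a
  correlated Gaussian with census-plausible means/SDs and a mild
  positive-semi-definite correlation matrix; two independent standard-normal
  decoys make variable selection non-trivial. Garden presence is Bernoulli
  with logit p = β₀ + Σβₖzₖ on the standardized covariates; the planted β
  (default intercept −1, slopes 0.9, −0.7, 0.8, 0.6, −0.6, 0.7 —
  moderate, mixed-sign effects giving ≈30% prevalence) is recorded on the
  table for recovery tests.
- **Gardens.** Clustered mode is a Thomas-like parent–offspring process
  (parents drawn ∝ planted garden probability, offspring N(0, 150 m));
  dispersed mode is a hard-core pattern with 120 m minimum spacing. Both
  place nodes preferentially in high-probability block groups.
- **Amenities.** Homogeneous Poisson layers (schools, parks, places of
  worship, community centres, libraries for the social surface;
  conservation lands and wetlands for the biophysical one) with the buffer
  radii of the social-amenity convention (schools/worship 500 m, others
  250 m) and intensities of order 0.3–2 points/km².

Everything derives from one integer seed through per-stage
`SeedSequence` streams; a fixed seed reproduces every output byte-for-byte.

What the generator does **not** emulate: spatial autocorrelation of
covariates between adjacent block groups, irregular census geography,
land-cover/amenity/covariate cross-correlations, and garden counts beyond
presence/absence. Passing recovery tests therefore demonstrate correctness
of the estimation chain under the stated model, not robustness to the messy
dependence structure of real census data.

## Resistance surfaces

- **Biophysical mapping.** Only the scale's endpoints are fixed by
  convention (canopy 1, buildings 180); the intermediate defaults
  (grass/shrub 5, bare soil 20, other paved 120, road/rail 150) grade the
  classes by permeability and are fully configurable. Water is nodata —
  removed from the circuit — rather than scored, with a high-resistance
  alternative available via the mapping table.
- **Screening.** Pairs with Spearman |ρ| > 0.60 lose the member with the
  weaker univariate rank association with garden presence (lexicographic
  tie-break). Constant covariates have undefined ρ and are dropped with a
  warning.
- **All-subsets fit.** Every covariate subset (≤ 2¹⁶ models) is fit by
  maximum-likelihood logistic regression on z-scored covariates
  (statsmodels), scored by AIC = 2k − 2logL and Akaike weight
  ω = exp(−Δ/2)/Σexp(−Δ/2). Complete separation raises an explicit
  convergence error.
- **Averaging.** The confidence set is the smallest weight-ordered prefix
  with Σω ≥ 0.97, with weights renormalized inside it (the subset
  convention; full-set weights are the other defensible reading).
  Importance(v) = Σ renormalized ω over set members containing v; the
  averaged standardized coefficient is the conditional weighted mean over
  those members.
- **Scoring.** Selected variables (importance ≥ 1.0 by default) are split
  at their 1/3 and 2/3 empirical quantiles and scored 10/20/30; a
  *positive* coefficient (favours gardens) puts the **top** tertile at the
  lowest resistance. Ties at a breakpoint fall to the lower group; an
  unsplittable (constant) variable is an error. With six variables the base
  spans 60–180; an off-by-default flag rescales linearly to [1, 180] for
  users who want the full shared range.
- **Reductions and edges.** Each covering amenity buffer multiplies
  resistance by 0.9; overlaps stack multiplicatively (order-independent),
  floored at 1. The boundary is padded by 1 km of edge-replicated cells,
  flagged so downstream sampling and statistics exclude the pad.

The pipeline's selection fallback: when no covariate attains importance 1.0
(common below ~500 block groups), the best-AIC model's covariates are used
and the fallback is recorded in the run manifest.

## Circuit solver

Edge conductance between orthogonal neighbours is g = 2/(r_i + r_j) — two
half-cell resistors in series; the mean-of-conductances alternative is a
flag. The default neighbourhood is 4 (exact match to lattice test oracles);
8-neighbour mode scales diagonals by 1/√2 for the longer path. Pairs are
all C(n,2) up to 500, else a seeded uniform sample of 500, equally
weighted; pairs spanning different graph components are skipped and logged.

Each connected component's Laplacian is factorized once (sparse LU) with a
fixed reference vertex grounded; each pair then costs two triangular solves
of b = e_s − e_t, and reported potentials are shifted so the target sits at
0 V. Direct solves are used up to 250k vertices, above which a
Jacobi-preconditioned conjugate-gradient solve with relative tolerance
10⁻⁶ takes over; every solution's residual ‖Lv − b‖∞ is checked. Per-cell
current density is ½Σ|g·Δv| over incident edges, with the source and
target pinned at exactly 1 A. Verified invariants (test suite +
acceptance script): agreement with a dense pseudo-inverse Laplacian oracle
to <10⁻⁸, Kirchhoff conservation to <10⁻⁶ A, reciprocity, Rayleigh
monotonicity, and pinch-point concentration (≥50% of current through a
1-cell gap in a high-resistance wall; measured ≈100%).

## Connectivity statistics

Min–max normalization is computed over the *sampled* values (the extracted
points), not the full raster — configurable. Sample points landing on
nodata in either layer are flagged invalid and counted, not silently
dropped. The combined score is the plain sum (range [0, 2]); the
square-root transform is stored for density plots of the zero-inflated
distribution; summaries report median ± SD per layer (an unusual pairing,
kept deliberately as the convention of this analysis style). The
directionality fit regresses log normalized biophysical on log normalized
social connectivity; points with a zero in either layer are dropped and
counted (log-of-zero), a swap-axes flag transposes the ratio, and the
slope is descriptive — no linear model is claimed. The high-high overlap
mask thresholds each layer at its own mean + 1 SD over valid cells and
reports both the mask and its area fraction. The summary table reports the
maximum over sampled points; the raster-wide maximum is available from the
maps directly.

## Hotspot analysis

Counts on a 500 m fishnet (nodes exactly on a shared edge go to the
smaller row-major cell index) feed the Gi* statistic with binary
fixed-distance-band weights (band 500 m, self included). Empty cells are
retained — excluding them would bias the global mean. z is already in SD
units, so classification is hot above +1 and cold below −1; a
median-centred variant of the threshold is available as a flag, since
"one SD from the median" is the other reading of this convention. When a
cell's band covers the whole study area the statistic is 0/0 and z is set
to 0 (the neighbourhood sum equals its expectation exactly). IDW
interpolation uses power 2 by default, returns centroid values exactly,
and is bounded by [min z, max z].

## Numerical and design details

- Rasters are stored as ESRI ASCII grids (text, georeferenced, explicit
  nodata); vectors as GeoJSON; tables as CSV — every artifact is
  plain-text and diffable, and the manifest lists SHA-256 digests.
- Degenerate inputs raise typed errors rather than producing NaNs:
  single-class outcomes, constant covariates/layers/counts, empty
  selections, all-nodata surfaces, zero-area boundaries.
- Problem sizes used in the shipped checks: 3–5-cell oracle grids, 2000
  block groups × 20 seeds for recovery, 80×80-cell scenarios with 12
  gardens × 10 seeds for the pattern contrasts, 1000 permutations for the
  Gi* null — sizes at which each property is sharply testable on a single
  CPU in seconds to a couple of minutes.

## Limitations

- The per-class biophysical resistance values and the IDW power are
  conventions, not estimates; conclusions sensitive to them should be
  checked across the configurable mapping.
- Logistic fits ignore spatial autocorrelation among block groups, so
  importance weights on real data would be anti-conservative.
- Equal pair weighting in cumulative current treats all garden pairs as
  exchangeable; distance- or size-weighted schemes are not implemented.
- Current-density sums are reported raw with `n_pairs` attached;
  cross-scenario comparison requires the user to normalize by pair count.
- Gi* p-values use the normal approximation without multiple-testing
  correction across cells, matching standard hotspot-tool behaviour.
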