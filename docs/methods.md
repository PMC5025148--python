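# Methods

This note documents the models, parameter choices and numerical decisions
behind `katydid_hotspots`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Scoring chart

The chart maps categorical traits to integers: threat T ∈ {LC:0, VU:1, EN:2,
CR:3}; mobility M ∈ {fully flighted:0, one sex or partially flighted:1,
flightless:2}; trophic level Tr ∈ {omnivorous:0, predatory:1, polyphagous
herbivore:2, monophagous herbivore:3}; life history LH is the image of M+Tr
under {0→0, 1–2→1, 3→2, 4–5→3}.  Distribution D is a decision list over the
range-coverage fractions of South Africa+Lesotho+Swaziland (`frac_SA`) and
southern Africa (`frac_sA`), the province count, and two flags:

1. D=3 if endemic and confined to ≤ 2 provinces;
2. D=2 if (endemic and frac_SA > 1/3) or (marginal in SA, frac_SA < 1/3,
   frac_sA > 2/3);
3. D=0 if frac_SA > 3/4 and frac_sA > 3/4 ("very common");
4. D=1 if (frac_SA > 2/3 and frac_sA > 2/3) or (not marginal, frac_SA ≤ 1/3,
   frac_sA > 2/3, ≤ 3 provinces);
5. otherwise the species is rejected with the full rule trace.

Two interpretation points.  The "very common" rule (>75 % both) is evaluated
before the numerically overlapping ">66 % both" clause of D=1, because it is
the more specific condition — otherwise no species could ever score 0.  The
numeric overlap between D=1's "0–33 % SA, >66 % sA" clause and D=2's
"marginal and very rare in SA, <33 % SA" clause is resolved by an explicit
`marginal_in_SA` flag; the chart's prose distinguishes the two by abundance
("very common" vs "very rare"), which is not derivable from the fractions.
All percentage thresholds are strict, as printed.

Trait-by-status comparisons use the tie-corrected Kruskal–Wallis H (scipy)
with a Nemenyi post-hoc in the chi-square approximation (tie-corrected,
valid for unequal group sizes) and a compact letter display at α = 0.05
(insert-and-absorb).  Categories with fewer than two members are excluded
and reported.

## Range metrics

Areas are measured on the authalic sphere (R = 6371.0088 km) through a
Lambert azimuthal equal-area projection centred on the species' point
centroid, so species at different latitudes are comparable without a fixed
national CRS.  EOO is the planar convex-hull area of the projected points;
AOO is 4 km² per distinct occupied 2×2 km cell on a grid whose origin sits
at a cell centre under the projection origin (a tight cluster therefore
occupies one cell).  Coincident or collinear localities have a degenerate
hull; EOO then falls back to the AOO value.  EOO < AOO is possible for thin
hulls and is flagged, not corrected.  Cell-origin sensitivity (IUCN guidance
allows optimising the grid origin) is not implemented.

The Criterion B screen uses only the range thresholds (CR: EOO<100 or
AOO<10; EN: EOO<5000 or AOO<500; VU: EOO<20000 or AOO<2000), without the
subcriteria on fragmentation or decline — real statuses, where available,
are inputs, not outputs.  Endemism is strict EOO < 5000 km², the EN cut-off;
`eoo_gap_profile` reports successive relative gaps (Δ/EOO) in the sorted EOO
values so the natural break motivating that threshold can be inspected.

## Gridding

The fishnet is aligned to integer degrees (origin (0,0), configurable),
cells clipped to the region, zero-intersection cells dropped, and land area
computed by the equal-area projection (graticule edges densified to 0.05°
before projecting, otherwise long chords cut corners).  Records map to cells
half-open: lon ∈ [lon0, lon0+Δ), lat ∈ [lat0, lat0+Δ).  Cell labels (letter
= latitude row from the north, number = longitude column from the west) are
cosmetic.  Richness counts and mean scores are species-level: record
multiplicity never weights a mean.  Cells without records are "no data"
(NaN), distinct from zero, and are excluded from every percentile threshold
and association denominator.

## Hotspot delineation and association

The top-decile rule takes the k-th largest value with k = ⌈0.10 n⌉ over
cells with data and includes all ties at that threshold, so the selected set
is at least k and exactly k when the threshold value is unique.  Count-based
hotspots are the union over the four richness measures ("and/or"); the
score-based set uses mean T+D+LH only.  Polygon inclusion rules are strict
(fraction > rule) with the area-computation tolerance 10⁻⁶ applied on both
sides, so an exactly-half-covered cell is excluded under the 50 % rule
regardless of projection round-off; the 100 % rule is full inclusion within
the same tolerance.  The default rule is 50 %.  χ² association uses the
Yates continuity correction by default (the stock behaviour of 2×2 tests in
R), with the uncorrected statistic behind a flag; degenerate tables (a zero
marginal) are rejected rather than reported as χ² = 0.

## Spatial regression

Pairwise measure models are generalized regressions of one diversity
measure on another plus cell land area, with spatially correlated errors,
fitted by penalized quasi-likelihood: iterate the working response
z = η + (y − μ)/μ and solve GLS under the working covariance

  Σ(θ, ρ) = W⁻¹ + θ·C(ρ),  C_ij = exp(−d_ij/ρ),  W = diag(μ),

i.e. observation-level noise plus a latent spatial field of relative
variance θ — the Breslow–Clayton working model for a GLMM with a spatially
correlated random effect.  The bounded mean-score response uses the Gaussian
variant (identity working response, Σ = I + θC).  ρ is profiled on a
20-point log grid spanning [0.1·median d, 2·max d] and refined by golden
section; θ on the log grid {0.0125 … 1.6}.  Model selection uses the REML
profile of the working model: the REML term log|XᵀΣ⁻¹X| is essential here —
under a pure ML profile (and under the superficially simpler
residual-correlation family W^{-1/2}CW^{-1/2}) the objective rises
monotonically toward the compound-symmetry limit as ρ grows, the range
estimate hits the grid cap and the slope attenuates ≈ 13 %.  With the
noise-plus-field family and REML, a planted slope of 0.5 on a 15×15 lattice
(Poisson counts, exponential field with range 2, field sd 0.3) is recovered
to 0.503 ± 0.038 over replicates.  Updates are damped (step cap 2 on the
linear predictor scale) and degenerate profile points are treated as −∞.
t-values use the REML dispersion; marginal r² is var(Xβ̂)/(var(Xβ̂)+σ²_d)
with σ²_d = ln(1 + 1/exp(β₀)) for the Poisson family (lognormal
approximation) and the total working residual variance for the Gaussian
variant.  ρ itself is weakly identified at n ≈ 100 cells; slopes are robust
to that, range estimates are not, and the latter should not be
over-interpreted.

Moran's I uses inverse great-circle-distance weights between cell centroids
(zero diagonal, no row standardisation), E[I] = −1/(n−1), and a seeded
two-sided permutation test centred on E[I].  The global-I reduction of a
distance-class correlogram is an interpretation, documented here.

## Phylogenetic comparative models

The tree is the taxonomy as nested polytomies (subfamily → genus → subgenus
→ species), every branch length 1; species without a subgenus attach at the
genus node.  A covariance matrix needs a root, so the basal subfamily
polytomy serves as one (a star at the root contributes zero shared path
between subfamilies).  Pagel's λ multiplies the off-diagonal of the Brownian
shared-path matrix; PGLS maximises the Gaussian ML profile over λ ∈ [0, 1]
by bounded search with explicit endpoint checks (boundary estimates λ = 0
are common and must be representable).  AIC = 2k − 2ℓ with k = coefficients
+ 1 (scale) + 1 when λ is estimated; ML (not REML) likelihoods so AIC is
comparable across fixed-effect structures.  Two-predictor models include the
interaction term and nest their main-effect models.  Integer scores are
treated as continuous responses — a standard but documented approximation
for ordinal trait indices.  Note λ = 0 reproduces OLS coefficients exactly
only on trees with equal tip depths (the GLS weights are then proportional
to identity); with mixed depths it is a weighted fit.

## Rarefaction

Sample-based accumulation uses the combinatorial expectation over species
incidences, E[S_t] = Σᵢ (1 − C(T−Tᵢ, t)/C(T, t)); individual-based
rarefaction the hypergeometric analogue.  Variances are the exact
conditional (subsampling) variances computed from pairwise joint-absence
probabilities — C(T−|Uᵢ∪Uⱼ|, t)/C(T, t) from the co-occurrence counts, and
C(N−Nᵢ−Nⱼ, n)/C(N, n) for individuals — so both moments agree with
exhaustive subset enumeration to 10⁻⁹ on small fixtures, and the CI
collapses to zero at full effort.  This conditional variance is a deliberate
choice over the unconditional variant (which requires an extrapolated total
richness): it is exactly testable and answers "how variable is a subsample
of *these* data".  CIs are normal ±1.96 sd.  Binomial coefficients are
evaluated through log-gamma.

## Synthetic data generator

The generator emulates the study conditions: 130 species (≈ 12 % DD), 1100
records, Red List marginals ≈ 57/13/8/11 % (LC/VU/EN/CR) among assessed
species, a 10°×8° region with a triangular coastline notch (forcing clipped
cells), hotspot polygons covering ≈ 30 % of the region, and an enrichment
factor of 4 on the placement odds of narrow-range specialists inside those
polygons.  Internals, in order:

- Taxonomy: a random nested partition into 10 subfamilies, 1–4 genera each,
  1–3 subgenera per genus; every species carries a subgenus, so the tree is
  ultrametric (depth 4).
- Ranges and status: a standard-normal latent vector with phylogenetic
  correlation λ = 0.7 on the taxonomy tree is binned by quantile into range
  classes matching the status marginals; a target EOO is drawn log-uniform
  within the class bounds, screened by Criterion B, perturbed one step with
  probability 0.05 (standing in for expert judgement and Criterion D), and a
  further 12 % of species are relabelled DD.
- D follows from the target EOO (<5000→3, <20000→2, <75000→1, else 0) and
  the trait-table fields (fractions, provinces, flags) are drawn so the
  scoring chart maps them back to exactly that D, exercising every rule
  route.  M and Tr come from latent vectors correlated 0.5 with the range
  latent (narrow-range species tend to be flightless specialists), binned to
  realistic marginals.
- Placement: the specialist pool is the top quarter of scorable species by
  D + LH.  Specialists aggregate around 6 micro-habitat core sites (distinct
  cells; kernel spread 0.12°) — the ecological picture is pockets of endemic
  vegetation in which range-restricted specialists co-occur.  Core sites are
  sampled uniformly and accepted with the enrichment odds of lying inside a
  hotspot polygon, then snapped to their cell centre; non-specialists are
  uniform over the region.  Kernel width scales as √(EOO_target/π)/1.6.
- Records: ≥ 2 per scorable species, the rest multinomial with weights
  proportional to kernel width (collection effort grows with range size, as
  in museum data); records are Gaussian around the kernel centre, resampled
  into the region.
- Ground truth: a species is "truly present" in a cell when its expected
  record count there (records × analytic bivariate-normal cell mass) is at
  least ln 2 — i.e. it is more likely than not to be collected at least
  once.  The planted hotspot cells are the top decile of the true per-cell
  mean T+D+LH under the same tie-inclusive rule the pipeline uses.

All draws run off per-stage child seeds spawned from the single
configuration seed, so any stage can be regenerated independently and equal
seeds give byte-identical outputs.

What passing tests show — and do not.  Recovery of the planted hotspot cells
(Jaccard ≥ 0.5 in ≥ 80 % of replicates at enrichment 4; no spurious
association at enrichment 1) shows the delineation machinery is correct and
has power under clustered, enriched placement with detection-saturated
sampling.  Real museum data add everything the generator omits: spatially
biased collecting effort (roads, coastlines), taxonomic revision noise,
range shapes that are not Gaussian kernels, non-independence of the hotspot
polygons from the biology, and far sparser sampling of the interior.  The
tests validate the software and the statistical behaviour of the methods,
not the ecological conclusions one would draw from any particular dataset.

## Problem sizes

Defaults were chosen so the whole suite exercises realistic sizes while
staying quick on a laptop: recovery runs use 100 replicates of the full
130-species pipeline, the PQL recovery simulation 200 replicates on a 15×15
lattice, PGLS recovery 200 replicates on 114 tips, and brute-force
enumeration oracles stay at ≤ 12 individuals / ≤ 4 samples where
enumeration is exact and instant.

## Known limitations

- EOO/AOO depend mildly on the projection centre; functions accept an
  explicit centre for strict monotonicity comparisons.
- The spatial range ρ and nugget-vs-field split are weakly identified at
  ~100 cells; only slopes and their t-values are treated as primary outputs.
- The λ estimate on binned (0–3) scores is attenuated relative to the
  latent-scale signal; recovery tests therefore simulate continuous traits.
- Criterion D (population-based) assessment is out of scope; screened
  statuses are range-only.
- No raster gridding or equal-area tessellation; cells are equal-angle with
  land-area covariates.
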