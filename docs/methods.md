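# Methods

## Problem and approach

Georeferenced genebank collections are spatially biased: some river basins
are sampled exhaustively, others barely at all. Any statistic whose
expectation grows with sample size (allelic richness above all) therefore
cannot be mapped directly. The pipeline addresses this in two steps:
neighborhood replication to obtain per-cell samples at all, and subsample
averaging to make the per-cell statistics comparable.

## Grid and circular neighborhoods

The analysis grid has 10-arcminute (1/6°) cells aligned to (−180°, −90°), so
cell indices are reproducible across runs and datasets. Cells are half-open
boxes `[west, east) × [south, north)`. Each individual is replicated into
every cell whose **center** lies within `diameter/2` (default 0.5°,
inclusive) of its location — for a point at a cell center this is the
29-cell discrete disc (offsets with `i² + j² ≤ 9` in cell units). Distances
are planar Euclidean in decimal degrees: the intended study regions are
equatorial, where one degree is ≈ 111 km in both axes, so great-circle
corrections would change assignments negligibly while complicating cell
algebra. Cells with fewer than `min_trees` individuals are discarded;
`min_trees="auto"` uses the median of per-cell counts, the same rule that
fixes the common subsample size.

Two distinct neighborhood constructions exist and are implemented
separately: diversity surfaces replicate **trees into cells** (a cell's
sample is every tree whose disc covers the cell center), whereas sPCA score
and membership rasters average/maximise over **trees within the disc of each
cell center**. For symmetric configurations they coincide; both are
brute-force-checked in the tests.

## Diversity statistics

All statistics are means over loci with data; loci without scored calls in a
sample are skipped rather than imputed as zero. Nei gene diversity uses the
plug-in `1 − Σ p̂²` without the `2n/(2n−1)` small-sample factor because size
comparability is achieved by subsampling to a common number of trees, not by
analytic correction. Locally common alleles use an occupancy screen over all
units (≤ 25 % of grid cells, or ≤ 2 clusters) and a within-unit frequency
criterion — inclusive (≥ 5 %) in grid mode, strict (> 5 %) in cluster mode;
the two modes deliberately differ. The occupancy denominator is the set of
*retained* cells.

## Bootstrap sample-bias correction

Per unit (cell or cluster), each statistic is the mean over `B = 1000`
subsamples of `n_trees` individuals drawn **without replacement** —
"bootstrap" by convention, repeated rarefaction in substance. Whole trees
(2 gene copies each) are subsampled, not individual copies, so heterozygosity
remains well defined; defaults are 8 trees = 16 copies per grid cell and the
smallest cluster size for clusters. Per-unit RNG substreams derive from
(master seed, unit id), making results independent of iteration order. A unit
of exactly `n_trees` individuals has a single possible subsample and is
reported with standard deviation exactly 0.

For allelic richness the subsample mean estimates the hypergeometric
rarefaction expectation `E = Σ_i [1 − C(N−N_i, g)/C(N, g)]`. Two effects
separate them slightly: tree pairing (the 16 copies arrive as 8 correlated
pairs rather than 16 independent draws) and missing data (a subsample can
hold fewer than g copies at a locus). On the synthetic scenario the
regression of bootstrap means on analytic values across ~1000 cells gives
slope ≈ 0.991 and r ≈ 0.9999, so the correction is unbiased to ~1 % — the
validation the acceptance script recomputes. For that comparison both sides
are restricted to the same locus set (full-unit copies ≥ g).

The occupancy screen of locally common alleles is evaluated once on
full-unit spectra; only the within-unit frequency criterion is averaged over
subsamples, since occupancy is a property of the whole layout, not of a
subsample. The same mechanism counts unit-private alleles present in each
subsample.

## Cleaning

Cleaning drops individuals without coordinates, then covariate outliers by
the reverse-jackknife gap test (Chapman 2005): standardised products of
adjacent sorted-value gaps with their distance to the mean, flagged beyond
the critical value `0.95·√n + 0.2`. Because each gap is standardised by the
spread of all gaps, simultaneous outliers of similar magnitude in both tails
mask one another within a single pass; the pass is therefore repeated on the
retained values until stable. The screen stays deliberately conservative for
n ≲ 20. Covariates are screened per column, single-pass by default
(iterative behind a flag), and all flagged individuals are removed with the
reason recorded in the cleaning report.

## Cluster analysis

The allele matrix codes each individual's relative dosage (0 / 0.5 / 1) per
observed allele, with missing loci imputed by column means; zero-variance
columns are dropped before PCA with a log note. The BIC scan uses
`BIC(k) = n·ln(WSS_k/n) + k·ln(n)` on PCA scores retaining the smallest
number of components explaining ≥ 95 % variance; the suggested k is the
largest positive second difference of the curve (the first pronounced
elbow), and the final k is the analyst's decision. DAPC memberships are
Gaussian posteriors with uniform priors in the whitened discriminant space
(identity within-group covariance), computed with log-sum-exp
normalisation. Cluster spectra include only members with membership ≥ 0.7
(inclusive). Nei (1972) distances pool identity sums over loci; the distance
is not a metric (triangle inequality may fail) and is +∞ for disjoint
spectra. Complete-linkage dendrograms are exported as ultrametric Newick
(leaf depth = merge height / 2) with the cophenetic correlation as fidelity
measure.

## Spatial PCA and permutation tests

The connection network is the Delaunay triangulation, binary and
row-normalised (exact duplicate coordinates are jittered by ≤ 1e−6° with a
fixed seed). sPCA eigen-decomposes `(1/n)·Xᵀ L X` with `L = (W+Wᵀ)/2`; for
row-normalised weights the total weight is n and each eigenvalue equals
`var(score) × Moran's I(score)` exactly (asserted to 1e−8 in tests, along
with trace conservation). The global/local Monte-Carlo test uses the total
positive (resp. absolute negative) eigenvalue mass as statistic and permutes
individuals over locations; it exploits that the non-zero spectrum of
`XᵀLX` equals that of `S UᵀLU S` from the thin SVD `X = USVᵀ`, so each
permutation costs one small symmetric eigendecomposition. The Mantel test
correlates off-diagonal upper triangles with one-sided p
`(1 + #{r_perm ≥ r_obs})/(1 + n_perm)`; exact enumeration of all n!
permutations is available for small n and is cross-checked against an
independent implementation in the tests. Both permutation tests are
calibrated: type-I error at α = 0.05 sits within [0.03, 0.07] over hundreds
of null simulations.

## Synthetic generator: what it emulates and what it does not

`cacao_like_scenario` produces 939 individuals × 96 loci from 10 populations
in an equatorial box (−80..−45°E, −20..10°N): Balding–Nichols drift F = 0.2
(two marginal lineages at F = 0.8 emulating domestication/refugium
bottlenecks), 8–16 alleles per locus, Gaussian spatial scatter around
hand-placed centers, one population sampled ~10× denser within a 0.35°
spread (a collection hotspot), 2 % missing calls, and isolation by distance
via per-copy admixture weights `∝ exp(−d/λ)` with λ = 0.5°. Population
sizes (81/40/45/81/81/81/81/290/80/79) keep the total at 939 with the
smallest confident cluster near 35–40.

The generator draws HWE genotypes at independent loci. It does **not**
emulate linkage, genotyping error or allele-size homoplasy, selfing or
clonal structure, stepwise mutation, or continuous (non-cluster) spatial
gradients beyond the exponential admixture. Passing tests therefore certify
the estimators and their bias correction under the stated model, not
robustness to those departures.

## Numerical choices

- Rarefaction terms use log-gamma differences; `C(N−N_i, g) = 0` when
  `N−N_i < g`.
- Subsampling uses argsort of uniform draws (vectorised sampling without
  replacement); per-replicate allele counts use flat `bincount` scatter.
- Bootstrap subsample selection orders individuals lexicographically by id,
  so results are invariant to table row order.
- Linkage ties are broken by scipy's canonical lowest-index rule.
- Raster nodata is −9999; ESRI ASCII values carry 6 significant digits,
  rows north to south.
- Problem sizes in tests and drivers (B = 1000, ~1000 retained cells,
  600-simulation calibrations) were chosen as the smallest sizes at which
  the Monte-Carlo errors are far below the effects being demonstrated.

## Known limitations

- Planar degree distances distort away from the equator; no projection
  support.
- The reverse-jackknife screen cannot flag a lone extreme value among fewer
  than ~20 observations (the standardised gap is bounded below the critical
  value), and masks equal-magnitude outliers in opposite tails within a
  pass.
- BIC elbow suggestion is a heuristic; for weakly structured data the curve
  has no elbow and the choice of k is genuinely the analyst's.
- Individual-level Nei distance (each tree a 2-copy population) is one of
  several reasonable individual distances; allele-sharing distance would be
  a drop-in alternative.
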