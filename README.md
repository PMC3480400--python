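# divgrid

Grid-based spatial analysis of microsatellite (SSR) genetic diversity for
georeferenced germplasm collections.

Collections of crop and tree genebank accessions are sampled very unevenly in
space, which makes naive maps of genetic diversity mostly maps of collecting
effort. `divgrid` implements a full landscape-genetics pipeline that corrects
for this:

- **Circular-neighborhood replication** — every individual is replicated into
  all 10-arcminute grid cells whose center lies within a 1° diameter disc
  around it, turning sparse points into mappable per-cell samples.
- **Bootstrap sample-bias correction** — per-cell statistics are means over
  B = 1000 subsamples of a fixed number of trees drawn *without replacement*
  (repeated rarefaction). For allelic richness this reproduces the exact
  hypergeometric rarefaction expectation
  `E[A_g] = Σ_i [1 − C(N−N_i, g)/C(N, g)]`
  at g gene copies, but unlike the closed form it corrects *any* statistic
  (Shannon index, Nei gene diversity `1 − Σ p_i²`, observed heterozygosity,
  locally common alleles).
- **Locally common alleles** — alleles restricted to ≤ 25 % of cells yet
  frequent (≥ 5 %) where they occur: a signature of isolated, possibly
  locally adapted populations.
- **Cluster analysis** — k-means on PCA scores with a BIC scan for k,
  DAPC-style membership probabilities, Nei (1972) distances
  `D = −ln(J_xy / √(J_x J_y))`, complete-linkage dendrograms with cophenetic
  correlation, and per-cluster membership / cluster-richness rasters.
- **Spatial PCA** — eigen-decomposition of `(1/n) Xᵀ((W+Wᵀ)/2)X` over a
  Delaunay connection network, whose axes maximise `var(score) × Moran's I`;
  Monte-Carlo tests for global/local structure; Mantel permutation tests of
  isolation by distance.
- **Synthetic data with truth** — a Balding–Nichols generator
  (`p_pop ~ Dirichlet(p_anc (1−F)/F)`) of refugium-structured, diploid HWE
  genotypes with bottlenecked lineages, isolation by distance, biased
  sampling and missing calls, so every step of the pipeline is testable
  against known truth.

## Worked example

The analysis drivers regenerate the bundled synthetic scenario (939
individuals × 96 SSR loci from 10 populations, two of them bottlenecked, one
sampled 10× denser) and run the full pipeline:

```sh
python analysis/01_simulate.py        # writes results/data/
python analysis/02_grid_diversity.py  # per-cell tables + rasters
python analysis/03_clusters.py        # clusters, dendrogram, Mantel test
python analysis/04_spatial_pca.py     # sPCA scores + raster
```

Output of `02_grid_diversity.py`:

```
replication: 26572 placements over 3689 cells; retained 1022 cells (28%) holding 19139 placements (72%)
bootstrap (B=1000) vs analytic rarefaction at g=16: slope 0.991, Pearson r 0.9999
```

Each of the 939 trees lands in ~29 cells; cells with fewer than 8 trees are
discarded; and the bootstrap means are statistically indistinguishable from
the exact rarefaction values — the sample-size correction works. From
`03_clusters.py`:

```
BIC elbow suggests k = 10 (retained 419 PCs); fitted at k = 10
adjusted Rand index vs planted truth: 0.953; 100.0% of individuals with membership > 0.7
lowest corrected richness: cluster 5 (true pop 2, 1.95), cluster 8 (true pop 1, 2.01)
complete-linkage dendrogram cophenetic correlation: 0.923
isolation by distance (Mantel, 250 individuals, 999 perms): r = 0.50, p = 0.001
```

The BIC scan recovers the planted number of populations, the DAPC
memberships recover the individuals' origins, and the two bottlenecked
lineages (true populations 1 and 2) rank lowest in bias-corrected allelic
richness — exactly the structure the generator planted.

## Layout

- `src/divgrid/` — library: `io`, `grid`, `diversity`, `bootstrap`,
  `structure`, `spatial`, `rasters`, `simulate`, `workflows`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
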