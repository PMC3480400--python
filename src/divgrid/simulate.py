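"""Synthetic georeferenced SSR datasets with known truth.

The generator emulates the structure the pipeline assumes in real
collections of a widely distributed tree crop: a handful of geographically
clumped, drift-differentiated populations (refugium lineages), two of them
strongly bottlenecked; isolation by distance through distance-decaying
admixture; heavily uneven sampling density; and sporadic missing calls.

Allele frequencies follow the Balding–Nichols model extended to
multi-allelic loci: ancestral frequencies are symmetric Dirichlet(1) draws
and each population's frequencies are Dirichlet(p_anc * (1-F)/F), so F acts
as a drift/bottleneck intensity (F -> 0: no drift; F -> 1: fixation).
Genotypes are diploid Hardy–Weinberg draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a continental SSR collection: 10 populations, 96 loci
    with 8–16 alleles each, drift F = 0.2 (0.8 for bottlenecked lineages),
    2% missing calls, coordinates in an equatorial box where degree-planar
    distances are adequate.
    """

    k_pops: int = 10
    n_loci: int = 96
    alleles_per_locus: tuple = (8, 16)
    drift: object = 0.2                 # scalar or per-population sequence
    centers: list | None = None         # (lon, lat) per population
    spatial_sd: object = 0.75           # degrees, scalar or per-population
    n_per_pop: object = 50              # scalar or per-population
    sampling_bias: list | None = None   # [(west, south, east, north, multiplier), ...]
    missing_rate: float = 0.02
    ibd_mixing: float = 0.0             # admixture decay length (degrees); 0 = off
    bounds: tuple = (-80.0, -45.0, -20.0, 10.0)  # lon_min, lon_max, lat_min, lat_max
    seed: int = 0

    def per_pop(self, value, dtype=float) -> np.ndarray:
        arr = np.asarray(value, dtype=dtype)
        if arr.ndim == 0:
            arr = np.full(self.k_pops, arr)
        if arr.size != self.k_pops:
            raise ValueError("per-population parameter has wrong length")
        return arr


@dataclass
class TruthTable:
    pop: np.ndarray          # (n,) true population index
    coords: np.ndarray       # (n, 2) lon/lat
    admixture: np.ndarray    # (n, k) row-stochastic source weights
    frequencies: list        # per pop: list per locus of allele freq arrays
    allele_labels: list      # per locus: integer labels (fragment sizes)
    centers: np.ndarray      # (k, 2)


def _default_centers(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Spread population centers in the bounding box with a minimum spacing."""
    w, e, s, n = config.bounds[0], config.bounds[1], config.bounds[2], config.bounds[3]
    min_dist = 0.25 * min(e - w, n - s)
    centers = []
    while len(centers) < config.k_pops:
        c = np.array([rng.uniform(w + 1, e - 1), rng.uniform(s + 1, n - 1)])
        if all(np.hypot(*(c - o)) >= min_dist for o in centers):
            centers.append(c)
        else:
            min_dist *= 0.995  # guarantee termination in crowded boxes
    return np.array(centers)


def simulate_frequencies(config: SimConfig, rng=None):
    """Ancestral and per-population allele frequencies (Balding–Nichols).

    Returns ``(pop_freqs, ancestral)``: ``pop_freqs[j][l]`` and
    ``ancestral[l]`` are frequency vectors over the locus's alleles.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.alleles_per_locus
    n_alleles = rng.integers(lo, hi + 1, size=config.n_loci)
    F = config.per_pop(config.drift)
    ancestral = [rng.dirichlet(np.ones(a)) for a in n_alleles]
    pop_freqs = []
    for j in range(config.k_pops):
        f = float(F[j])
        freqs = []
        for p_anc in ancestral:
            if f <= 1e-9:          # no-drift limit
                freqs.append(p_anc.copy())
            elif f >= 1 - 1e-12:   # fixation limit
                fixed = np.zeros_like(p_anc)
                fixed[rng.choice(p_anc.size, p=p_anc)] = 1.0
                freqs.append(fixed)
            else:
                freqs.append(rng.dirichlet(p_anc * (1 - f) / f))
        pop_freqs.append(freqs)
    return pop_freqs, ancestral


def simulate_individuals(frequencies, config: SimConfig, rng=None):
    """Coordinates, admixture and HWE genotypes for every individual.

    Coordinates are bivariate normal around each population's center. With
    ``ibd_mixing`` > 0 each gene copy's source population is drawn with
    weights exp(-d/lambda) over distances d to all centers, which produces
    isolation by distance; otherwise copies come from the home population
    only. Missing genotypes are masked whole-pair at ``missing_rate``.
    Returns ``(GenotypeTable, passports DataFrame, TruthTable)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    k, L = config.k_pops, config.n_loci
    centers = (np.asarray(config.centers, dtype=float) if config.centers is not None
               else _default_centers(config, rng))
    sds = config.per_pop(config.spatial_sd)
    ns = config.per_pop(config.n_per_pop, dtype=int).astype(int)
    if config.sampling_bias:
        for w, s, e, n, mult in config.sampling_bias:
            inside = ((centers[:, 0] >= w) & (centers[:, 0] < e)
                      & (centers[:, 1] >= s) & (centers[:, 1] < n))
            ns = np.where(inside, np.maximum(1, np.round(ns * mult)).astype(int), ns)

    pop = np.repeat(np.arange(k), ns)
    n = int(ns.sum())
    coords = np.empty((n, 2))
    for j in range(k):
        m = pop == j
        coords[m] = centers[j] + rng.normal(0.0, sds[j], size=(int(m.sum()), 2))

    if config.ibd_mixing > 0:
        d = np.hypot(coords[:, 0, None] - centers[None, :, 0],
                     coords[:, 1, None] - centers[None, :, 1])
        w = np.exp(-d / config.ibd_mixing)
        admix = w / w.sum(axis=1, keepdims=True)
    else:
        admix = np.zeros((n, k))
        admix[np.arange(n), pop] = 1.0

    labels = [np.array([150 + 2 * a for a in range(len(frequencies[0][l]))])
              for l in range(L)]
    cum_admix = np.cumsum(admix, axis=1)
    u_src = rng.random((n, L, 2))
    src = (u_src[:, :, :, None] > cum_admix[:, None, None, :]).sum(axis=3)
    calls = np.empty((n, L, 2), dtype=np.int64)
    for l in range(L):
        A = len(labels[l])
        cum = np.cumsum(np.array([frequencies[j][l] for j in range(k)]), axis=1)  # (k, A)
        u = rng.random((n, 2))
        cs = cum[src[:, l, :]]                       # (n, 2, A)
        idx = (u[:, :, None] > cs).sum(axis=2).clip(max=A - 1)
        calls[:, l, :] = labels[l][idx]
    if config.missing_rate > 0:
        miss = rng.random((n, L)) < config.missing_rate
        calls[miss] = -1

    ids = [f"ind_{i:04d}" for i in range(n)]
    genotypes = GenotypeTable(ids, [f"locus_{l:03d}" for l in range(L)], calls)
    passports = pd.DataFrame({"id": ids, "lon": coords[:, 0], "lat": coords[:, 1]})
    truth = TruthTable(pop=pop, coords=coords, admixture=admix,
                       frequencies=frequencies, allele_labels=labels,
                       centers=centers)
    return genotypes, passports, truth


# Hand-placed refugium-like centers in an Amazon-like box: a dense western
# hotspot region, two bottlenecked lineages at the range margins (a
# domesticated north-western one and a north-eastern one), and the rest
# spread over the basin.
_CACAO_CENTERS = [
    (-74.5, -8.5),   # pop 0: western, diverse
    (-79.0, 8.5),    # pop 1: NW margin, strong bottleneck (Criollo-like)
    (-53.0, 4.0),    # pop 2: NE margin, bottleneck (Guiana-like)
    (-65.0, -3.0),   # pop 3: central river
    (-47.0, -13.0),  # pop 4: SE margin
    (-76.0, -7.0),   # pop 5: Andean foothills
    (-63.0, -11.0),  # pop 6: S margin
    (-73.2, -4.2),   # pop 7: sampling hotspot (Iquitos-like), 10x denser
    (-74.8, -3.5),   # pop 8: near hotspot
    (-76.5, -1.5),   # pop 9: NW Amazon
]
_CACAO_N = [81, 40, 45, 81, 81, 81, 81, 290, 80, 79]       # sums to 939
_CACAO_F = [0.2, 0.8, 0.8, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2]
_CACAO_SD = [0.8, 0.5, 0.6, 0.8, 0.8, 0.8, 0.8, 0.35, 0.5, 0.6]


def cacao_like_config(seed: int = 42) -> SimConfig:
    return SimConfig(
        k_pops=10, n_loci=96, alleles_per_locus=(8, 16),
        drift=_CACAO_F, centers=_CACAO_CENTERS, spatial_sd=_CACAO_SD,
        n_per_pop=_CACAO_N, missing_rate=0.02, ibd_mixing=0.5, seed=seed,
    )


def cacao_like_scenario(seed: int = 42):
    """939 individuals x 96 loci over 10 refugium-structured populations.

    Two bottlenecked lineages (F = 0.8) sit at the range margins; one
    hotspot population is sampled ~10x denser (n = 290 within a 0.35-degree
    spread) than the rest, reproducing strongly uneven collection density.
    Returns ``(genotypes, passports, truth, config)``.
    """
    config = cacao_like_config(seed)
    rng = np.random.default_rng(seed)
    freqs, _ = simulate_frequencies(config, rng)
    genotypes, passports, truth = simulate_individuals(freqs, config, rng)
    return genotypes, passports, truth, config


def expected_cell_richness(truth: TruthTable, cells: dict, id_index: dict,
                           g: int = 16) -> pd.Series:
    """Truth-derived expected allelic richness per cell at g gene copies.

    Uses each cell's mixture of true source frequencies (admixture-weighted)
    and the binomial approximation E = sum_a [1 - (1 - p_a)^g], a noiseless
    reference surface for rank comparisons with the estimated one.
    """
    out = {}
    k = truth.admixture.shape[1]
    for key, ids in cells.items():
        rows = np.array([id_index[i] for i in ids])
        w = truth.admixture[rows].mean(axis=0)  # (k,)
        vals = []
        for l, lab in enumerate(truth.allele_labels):
            p = sum(w[j] * truth.frequencies[j][l] for j in range(k))
            vals.append(float(np.sum(1.0 - (1.0 - p) ** g)))
        out[key] = float(np.mean(vals))
    return pd.Series(out)
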