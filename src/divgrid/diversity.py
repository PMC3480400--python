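"""Per-sample SSR diversity statistics.

All statistics operate on an :class:`AlleleCountSpectrum` (per-locus gene-copy
counts) and are reported as means over loci with data, so a locus with no
non-missing calls in the sample never deflates the value. Allelic richness is
sample-size dependent; :func:`rarefaction_expected_alleles` gives the exact
hypergeometric expectation of the number of distinct alleles in a subsample of
g gene copies, the standard way to compare richness across unequal samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import GenotypeTable


@dataclass
class AlleleCountSpectrum:
    """Per-locus allele -> gene-copy count tables for one sample of individuals."""

    loci: list
    counts: list  # per locus: dict allele_label -> count (only non-missing copies)

    @property
    def n_copies(self) -> np.ndarray:
        return np.array([sum(c.values()) for c in self.counts], dtype=np.int64)

    def nonempty(self) -> np.ndarray:
        return self.n_copies > 0

    def frequencies(self, locus_index: int) -> dict:
        c = self.counts[locus_index]
        n = sum(c.values())
        return {a: k / n for a, k in c.items()} if n else {}


def allele_counts(genotypes: GenotypeTable, individual_ids=None) -> AlleleCountSpectrum:
    """Gene-copy counts per locus over the given individuals (missing pairs excluded)."""
    if individual_ids is None:
        rows = np.arange(genotypes.n_individuals)
    else:
        rows = genotypes.rows_of(individual_ids)
    counts = []
    for l in range(genotypes.n_loci):
        col = genotypes.calls[rows, l, :].ravel()
        col = col[col >= 0]
        alleles, k = np.unique(col, return_counts=True)
        counts.append({int(a): int(c) for a, c in zip(alleles, k)})
    return AlleleCountSpectrum(loci=list(genotypes.loci), counts=counts)


def _per_locus_mean(values, mask) -> float:
    vals = np.asarray(values, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("no locus has any data in this sample")
    return float(vals.mean())


def allelic_richness(spectrum: AlleleCountSpectrum) -> float:
    """Mean number of distinct alleles per locus (loci with data only)."""
    return _per_locus_mean([len(c) for c in spectrum.counts], spectrum.nonempty())


def nei_gene_diversity(spectrum: AlleleCountSpectrum) -> float:
    """Nei (1973) gene diversity: mean per-locus 1 - sum p_i^2.

    Plug-in estimator without the 2n/(2n-1) small-sample correction; size
    comparability is handled upstream by subsampling to a common g.
    """
    n = spectrum.n_copies
    vals = []
    for c, nc in zip(spectrum.counts, n):
        if nc:
            p = np.array(list(c.values()), dtype=float) / nc
            vals.append(1.0 - np.sum(p * p))
        else:
            vals.append(np.nan)
    return _per_locus_mean(vals, spectrum.nonempty())


def shannon_index(spectrum: AlleleCountSpectrum) -> float:
    """Mean per-locus Shannon information -sum p_i ln p_i (natural log)."""
    n = spectrum.n_copies
    vals = []
    for c, nc in zip(spectrum.counts, n):
        if nc:
            p = np.array(list(c.values()), dtype=float) / nc
            vals.append(float(-np.sum(p * np.log(p))))
        else:
            vals.append(np.nan)
    return _per_locus_mean(vals, spectrum.nonempty())


def observed_heterozygosity(genotypes: GenotypeTable, individual_ids=None) -> float:
    """Mean per-locus fraction of heterozygous individuals among scored ones."""
    if individual_ids is None:
        rows = np.arange(genotypes.n_individuals)
    else:
        rows = genotypes.rows_of(individual_ids)
    calls = genotypes.calls[rows]
    scored = calls[:, :, 0] >= 0
    het = scored & (calls[:, :, 0] != calls[:, :, 1])
    n_scored = scored.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = het.sum(axis=0) / n_scored
    return _per_locus_mean(frac, n_scored > 0)


def rarefaction_expected_alleles_locus(counts: dict, g: int) -> float:
    """Exact E[# distinct alleles in g gene copies drawn without replacement].

    E = sum_i [1 - C(N - N_i, g) / C(N, g)] with N total copies at the locus
    and N_i the count of allele i (hypergeometric absence probability).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    N = sum(counts.values())
    if N < g:
        raise ValueError(f"locus has {N} copies < g={g}")
    ni = np.array(list(counts.values()), dtype=float)
    rest = N - ni
    # log C(rest, g) - log C(N, g); C(rest, g) = 0 when rest < g
    with np.errstate(divide="ignore"):
        log_absent = (gammaln(rest + 1) - gammaln(g + 1) - gammaln(rest - g + 1)
                      - (gammaln(N + 1) - gammaln(g + 1) - gammaln(N - g + 1)))
    p_absent = np.where(rest >= g, np.exp(log_absent), 0.0)
    return float(np.sum(1.0 - p_absent))


def rarefaction_expected_alleles(spectrum: AlleleCountSpectrum, g: int) -> float:
    """Mean over included loci of the rarefaction expectation at g copies.

    Loci with fewer than g copies are excluded (they cannot be rarefied to g);
    a warning reports how many were skipped.
    """
    n = spectrum.n_copies
    included = n >= g
    if not included.any():
        raise ValueError(f"no locus has at least g={g} gene copies")
    if (~included & (n > 0)).any():
        warnings.warn(f"{int((~included & (n > 0)).sum())} loci with < {g} copies "
                      "excluded from rarefaction")
    vals = [rarefaction_expected_alleles_locus(c, g) if ok else np.nan
            for c, ok in zip(spectrum.counts, included)]
    return _per_locus_mean(vals, included)


def private_alleles(spectra_by_group: dict) -> dict:
    """Per group: mean per-locus count of alleles found in that group only."""
    if len(spectra_by_group) < 2:
        raise ValueError("private alleles need at least 2 groups")
    names = list(spectra_by_group)
    first = spectra_by_group[names[0]]
    L = len(first.loci)
    out = {}
    for g in names:
        spec = spectra_by_group[g]
        privates = 0
        for l in range(L):
            mine = set(spec.counts[l])
            others = set()
            for h in names:
                if h != g:
                    others |= set(spectra_by_group[h].counts[l])
            privates += len(mine - others)
        out[g] = privates / L
    return out


def locally_common_alleles(spectra_by_unit: dict, occupancy_max_frac=None,
                           occupancy_max_units=None, freq_min: float = 0.05,
                           strict: bool = False) -> dict:
    """Per unit: mean per-locus count of locally common alleles.

    An allele qualifies for unit U when (a) it occurs in few units overall —
    at most ``occupancy_max_frac`` of all units (grid mode, e.g. 25% of
    cells) or at most ``occupancy_max_units`` units (cluster mode, e.g. 1–2
    clusters) — and (b) it is frequent within U: frequency >= ``freq_min``
    (inclusive, grid mode) or > ``freq_min`` when ``strict`` (cluster mode).
    """
    if (occupancy_max_frac is None) == (occupancy_max_units is None):
        raise ValueError("give exactly one of occupancy_max_frac / occupancy_max_units")
    names = list(spectra_by_unit)
    n_units = len(names)
    if n_units == 1:
        warnings.warn("single unit: every present allele trivially passes occupancy")
    max_units = (occupancy_max_units if occupancy_max_units is not None
                 else occupancy_max_frac * n_units)
    L = len(spectra_by_unit[names[0]].loci)
    occupancy: list[dict] = [{} for _ in range(L)]
    for u in names:
        spec = spectra_by_unit[u]
        for l in range(L):
            for a in spec.counts[l]:
                occupancy[l][a] = occupancy[l].get(a, 0) + 1
    out = {}
    for u in names:
        spec = spectra_by_unit[u]
        total = 0
        for l in range(L):
            freqs = spec.frequencies(l)
            for a, f in freqs.items():
                if occupancy[l][a] <= max_units and (f > freq_min if strict else f >= freq_min):
                    total += 1
        out[u] = total / L
    return out
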