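"""Sample-bias correction by repeated subsampling without replacement.

Grid cells (and clusters) contain very different numbers of individuals, so
raw diversity statistics are not comparable between them. Each unit's
statistics are therefore reported as the mean over B subsamples of a fixed
number of trees drawn without replacement — a repeated-rarefaction scheme
that, unlike the closed-form rarefaction of allelic richness, corrects the
sample bias of ANY statistic. For allelic richness the subsample mean is an
unbiased Monte-Carlo estimate of the hypergeometric rarefaction expectation,
which :func:`validate_against_rarefaction` checks by regression.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import AlleleCountSpectrum, rarefaction_expected_alleles_locus
from .grid import NeighborhoodAssignment
from .io import GenotypeTable

STAT_NAMES = ("allelic_richness", "shannon", "nei_diversity", "obs_heterozygosity")


@dataclass
class BootstrapConfig:
    """Subsampling scheme: ``n_trees`` per draw (2*n_trees gene copies), B draws."""

    n_trees: int = 8
    B: int = 1000
    seed: int = 0
    statistics: tuple = STAT_NAMES

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.B < 1:
            raise ValueError("n_trees and B must be >= 1")

    @property
    def g(self) -> int:
        return 2 * self.n_trees


@dataclass
class MaskedAlleleStat:
    """A per-replicate count of alleles from a fixed eligibility mask.

    ``mask[l, a]`` marks alleles (in compact per-locus coding) eligible for
    the unit — e.g. alleles passing the locally-common occupancy criterion,
    or alleles private to the unit. Within each subsample the allele is
    counted when its frequency passes ``freq_min`` (strict ``>`` or
    inclusive ``>=``); reported as mean count per locus.
    """

    name: str
    mask: np.ndarray
    freq_min: float = 0.0
    strict: bool = True


def _unit_counts(codes: np.ndarray, a_max: int, rows: np.ndarray) -> np.ndarray:
    """Full-sample allele count array (L, a_max) for one unit."""
    _, L, _ = codes.shape
    sub = codes[rows]  # (m, L, 2)
    c = sub.transpose(1, 0, 2).reshape(L, -1)
    valid = c >= 0
    li = np.broadcast_to(np.arange(L)[:, None], c.shape)
    flat = (li * a_max + c)[valid]
    return np.bincount(flat, minlength=L * a_max).reshape(L, a_max)


def _replicate_stats(codes: np.ndarray, a_max: int, rows: np.ndarray,
                     n_trees: int, B: int, rng: np.random.Generator,
                     statistics, locus_mask=None, masked_stats=()) -> dict:
    """Evaluate statistics on B subsamples of ``n_trees`` rows; (B,) per stat."""
    n, L = rows.size, codes.shape[1]
    if n < n_trees:
        raise ValueError(f"unit has {n} individuals < n_trees={n_trees}")
    if n == n_trees:
        idx = np.broadcast_to(np.arange(n), (B, n)).copy()
    else:
        idx = np.argsort(rng.random((B, n)), axis=1)[:, :n_trees]
    sub = codes[rows[idx]]  # (B, t, L, 2)
    a1, a2 = sub[..., 0], sub[..., 1]  # (B, t, L)

    copies = sub.transpose(0, 2, 1, 3).reshape(B, L, -1)
    valid = copies >= 0
    bi = np.arange(B)[:, None, None]
    li = np.arange(L)[None, :, None]
    flat = ((bi * L + li) * a_max + copies)[valid]
    counts = np.bincount(flat, minlength=B * L * a_max).reshape(B, L, a_max)
    n_copies = counts.sum(axis=2)

    has = n_copies > 0
    if locus_mask is not None:
        has = has & locus_mask[None, :]
    denom = has.sum(axis=1).astype(float)
    if (denom == 0).any():
        raise ValueError("a subsample has no locus with data")

    present = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n_copies[:, :, None]
    out = {}
    for stat in statistics:
        if stat == "allelic_richness":
            vals = present.sum(axis=2).astype(float)
        elif stat == "nei_diversity":
            vals = 1.0 - np.nansum(p * p, axis=2)
        elif stat == "shannon":
            with np.errstate(invalid="ignore", divide="ignore"):
                plogp = np.where(counts > 0, p * np.log(np.where(counts > 0, p, 1.0)), 0.0)
            vals = -plogp.sum(axis=2)
        elif stat == "obs_heterozygosity":
            scored = a1 >= 0
            het = scored & (a1 != a2)
            ns = scored.sum(axis=1)
            with np.errstate(invalid="ignore"):
                vals = het.sum(axis=1) / ns
            vals = np.where(ns > 0, vals, 0.0)
            hh = has & (ns > 0)
            dh = hh.sum(axis=1).astype(float)
            out[stat] = np.where(hh, vals, 0.0).sum(axis=1) / dh
            continue
        else:
            raise ValueError(f"unknown statistic {stat!r}")
        out[stat] = np.where(has, vals, 0.0).sum(axis=1) / denom
    for ms in masked_stats:
        passes = present & ms.mask[None, :, :]
        if ms.strict:
            passes &= p > ms.freq_min
        else:
            passes &= p >= ms.freq_min
        vals = passes.sum(axis=2).astype(float)
        out[ms.name] = np.where(has, vals, 0.0).sum(axis=1) / denom
    return out


def bootstrap_statistic(genotypes: GenotypeTable, ids_in_unit, stat,
                        config: BootstrapConfig, rng=None):
    """Mean and sd of a statistic over B subsamples of n_trees individuals.

    ``stat`` is a registered statistic name (vectorized path) or a callable
    ``stat(genotypes, ids) -> float`` (generic path). A unit smaller than
    n_trees is skipped: a warning is emitted and ``(nan, nan)`` returned,
    mirroring the discarding of under-sampled cells.
    """
    ids = sorted(ids_in_unit, key=str)  # canonical order: row-order invariant
    if len(ids) < config.n_trees:
        warnings.warn(f"unit with {len(ids)} individuals < n_trees={config.n_trees}: skipped")
        return (float("nan"), float("nan"))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if callable(stat):
        vals = np.empty(config.B)
        arr = np.array(ids, dtype=object)
        for b in range(config.B):
            pick = rng.choice(arr, size=config.n_trees, replace=False)
            vals[b] = stat(genotypes, list(pick))
    else:
        enc = genotypes.encoded()
        rows = genotypes.rows_of(ids)
        vals = _replicate_stats(enc.codes, enc.a_max, rows, config.n_trees,
                                config.B, rng, [stat])[stat]
    if len(ids) == config.n_trees:  # one possible subsample: exactly no spread
        return float(vals.mean()), 0.0
    return float(vals.mean()), float(vals.std(ddof=0))


def _cell_rng(seed: int, key) -> np.random.Generator:
    """Substream derived from (master seed, unit key): independent of iteration order."""
    parts = [int(seed)]
    for k in (key if isinstance(key, tuple) else (key,)):
        if isinstance(k, (int, np.integer)):
            parts.append(int(k) + 2**20)
        else:  # stable across processes (unlike hash())
            parts.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(np.random.SeedSequence(parts))


def unit_bootstrap_table(genotypes: GenotypeTable, units: dict,
                         config: BootstrapConfig, locus_min_copies=None,
                         locally_common=None, include_private=False) -> pd.DataFrame:
    """Bootstrap-corrected statistics for arbitrary units (cells or clusters).

    ``units`` maps unit key -> individual ids. ``locus_min_copies`` restricts
    every statistic of a unit to loci with at least that many full-unit gene
    copies (used to align with rarefaction at g). ``locally_common`` is a
    dict of :func:`divgrid.diversity.locally_common_alleles`-style criteria
    (``occupancy_max_frac`` or ``occupancy_max_units``, ``freq_min``,
    ``strict``); the occupancy screen is evaluated ONCE on full-unit spectra,
    only the within-unit frequency criterion is averaged over subsamples.
    ``include_private`` adds the mean count of unit-private alleles present
    in the subsample.
    """
    enc = genotypes.encoded()
    keys = sorted(units)
    row_sets = {k: genotypes.rows_of(sorted(units[k], key=str)) for k in keys}
    full_counts = {k: _unit_counts(enc.codes, enc.a_max, row_sets[k]) for k in keys}

    lc_mask = None
    if locally_common is not None:
        occ = sum((full_counts[k] > 0).astype(int) for k in keys)
        if "occupancy_max_units" in locally_common and locally_common["occupancy_max_units"]:
            max_units = locally_common["occupancy_max_units"]
        else:
            max_units = locally_common["occupancy_max_frac"] * len(keys)
        lc_mask = (occ >= 1) & (occ <= max_units)

    records = []
    for k in keys:
        rows = row_sets[k]
        if rows.size < config.n_trees:
            warnings.warn(f"unit {k!r} with {rows.size} individuals skipped")
            continue
        locus_mask = None
        if locus_min_copies is not None:
            locus_mask = full_counts[k].sum(axis=1) >= locus_min_copies
        masked = []
        if lc_mask is not None:
            masked.append(MaskedAlleleStat("locally_common", lc_mask,
                                           locally_common.get("freq_min", 0.05),
                                           locally_common.get("strict", False)))
        if include_private:
            others = sum(full_counts[h] for h in keys if h != k)
            priv = (full_counts[k] > 0) & (others == 0)
            masked.append(MaskedAlleleStat("private_alleles", priv, 0.0, True))
        rng = _cell_rng(config.seed, k)
        vals = _replicate_stats(enc.codes, enc.a_max, rows, config.n_trees,
                                config.B, rng, config.statistics,
                                locus_mask=locus_mask, masked_stats=masked)
        rec = {"unit": k, "n_individuals": int(rows.size)}
        single = rows.size == config.n_trees  # one possible subsample
        for name, v in vals.items():
            rec[name] = float(v.mean())
            rec[f"{name}_sd"] = 0.0 if single else float(v.std(ddof=0))
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("unit")


def gridwide_bootstrap(assignment: NeighborhoodAssignment, genotypes: GenotypeTable,
                       config: BootstrapConfig, locus_min_copies=None,
                       locally_common=None) -> pd.DataFrame:
    """One row of bootstrap-corrected statistics per retained grid cell.

    ``locally_common`` defaults to the grid-mode rule (allele in at most 25%
    of cells, within-cell frequency >= 5% inclusive) when the statistic list
    requests it; pass a dict to override. Deterministic given the config
    seed: each cell uses an RNG substream derived from (seed, cell id).
    """
    if locally_common is None and "locally_common" in config.statistics:
        locally_common = {"occupancy_max_frac": 0.25, "freq_min": 0.05, "strict": False}
    stats = tuple(s for s in config.statistics if s != "locally_common")
    cfg = BootstrapConfig(n_trees=config.n_trees, B=config.B, seed=config.seed,
                          statistics=stats)
    table = unit_bootstrap_table(genotypes, assignment.cells, cfg,
                                 locus_min_copies=locus_min_copies,
                                 locally_common=locally_common)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["cell_col", "cell_row"])
    return table


def cell_rarefaction_expectation(genotypes: GenotypeTable, units: dict, g: int) -> pd.Series:
    """Analytic rarefaction expectation of richness at g copies per unit.

    Mean over loci with at least g full-unit copies — the same locus set the
    bootstrap table uses when ``locus_min_copies=g``.
    """
    enc = genotypes.encoded()
    out = {}
    for k in sorted(units):
        counts = _unit_counts(enc.codes, enc.a_max, genotypes.rows_of(units[k]))
        vals = []
        for l in range(counts.shape[0]):
            c = {a: int(x) for a, x in enumerate(counts[l]) if x > 0}
            if sum(c.values()) >= g:
                vals.append(rarefaction_expected_alleles_locus(c, g))
        if vals:
            out[k] = float(np.mean(vals))
    return pd.Series(out)


def validate_against_rarefaction(table: pd.DataFrame, analytic: pd.Series):
    """OLS slope and Pearson r of bootstrap richness vs analytic rarefaction.

    ``table`` must carry an ``allelic_richness`` column aligned (by unit key)
    with the ``analytic`` expectations. Both near 1 certify that B replicates
    suffice and that subsampling whole trees matches gene-copy rarefaction.
    """
    common = table.index.intersection(analytic.index)
    if len(common) < 3:
        raise ValueError("need at least 3 units for the validation regression")
    x = analytic.loc[common].to_numpy(dtype=float)
    y = table.loc[common, "allelic_richness"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in validation vectors")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue)
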