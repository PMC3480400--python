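"""Reading, validation and cleaning of SSR genotype and passport tables.

Genotypes are diploid multi-allelic microsatellite calls: two integer allele
labels (fragment sizes) per individual per locus, with whole-pair missing
data. Passports carry per-individual WGS84 decimal-degree coordinates and
optional numeric covariates (e.g. bioclimatic values) used for outlier-based
cleaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel used internally for a missing allele call
MISSING = -1

#: allele tokens treated as missing by default (common SSR conventions)
DEFAULT_MISSING_CODES = (0, -9)


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with integer allele
    labels (e.g. fragment sizes); a missing genotype is stored as
    ``(-1, -1)`` — half-missing pairs are normalised to fully missing.
    Heterozygote pairs are unordered: (a, b) is stored sorted so that
    (a, b) == (b, a).
    """

    ids: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.loci = [str(l) for l in self.loci]
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci x 2"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        # normalise: any half-missing pair becomes fully missing; sort pairs
        miss = (self.calls < 0).any(axis=2)
        self.calls = np.sort(self.calls, axis=2)
        self.calls[miss] = MISSING
        self._row_of = {ind: r for r, ind in enumerate(self.ids)}
        self._encoded = None

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def rows_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._row_of[str(i)] for i in ids], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown individual id {e}") from None

    def subset(self, ids) -> "GenotypeTable":
        rows = self.rows_of(ids)
        return GenotypeTable([self.ids[r] for r in rows], list(self.loci),
                             self.calls[rows].copy())

    def encoded(self):
        """Per-locus compact allele codes, cached (see :func:`encode_table`)."""
        if self._encoded is None:
            self._encoded = encode_table(self)
        return self._encoded

    def to_csv(self, path) -> None:
        """Write the wide two-columns-per-locus CSV dialect (0 = missing)."""
        cols = {"id": self.ids}
        for j, locus in enumerate(self.loci):
            a = self.calls[:, j, 0].copy()
            b = self.calls[:, j, 1].copy()
            a[a == MISSING] = 0
            b[b == MISSING] = 0
            cols[f"{locus}_1"] = a
            cols[f"{locus}_2"] = b
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass(frozen=True)
class EncodedGenotypes:
    """Genotype calls recoded to per-locus compact allele indices.

    ``codes[i, l, s]`` is the index of the allele in ``labels[l]`` or -1 if
    missing; ``a_max`` is ``max(len(labels[l]))`` — the width needed for
    one-hot allele count arrays.
    """

    codes: np.ndarray  # (n, L, 2) int32
    labels: list       # list of np.ndarray of allele labels per locus
    a_max: int


def encode_table(table: GenotypeTable) -> EncodedGenotypes:
    n, L, _ = table.calls.shape
    codes = np.full((n, L, 2), -1, dtype=np.int32)
    labels = []
    for l in range(L):
        col = table.calls[:, l, :]
        present = col[col >= 0]
        lab = np.unique(present)
        labels.append(lab)
        if lab.size:
            idx = np.searchsorted(lab, col.clip(min=lab.min()))
            codes[:, l, :] = np.where(col >= 0, idx, -1)
    a_max = max((len(l) for l in labels), default=1) or 1
    return EncodedGenotypes(codes=codes, labels=labels, a_max=a_max)


@dataclass
class CleaningReport:
    n_input: int
    n_retained: int
    n_removed_missing_coords: int
    n_removed_outliers: int
    removed_ids: dict = field(default_factory=dict)  # id -> reason


def _parse_allele(token, missing_codes) -> int:
    try:
        v = int(float(token))
    except (TypeError, ValueError):
        return MISSING
    return MISSING if v in missing_codes else v


def read_genotype_table(path, dialect: str = "wide",
                        missing_codes=DEFAULT_MISSING_CODES) -> GenotypeTable:
    """Read a genotype table.

    dialect "wide": header row ``id,<locus>_1,<locus>_2,...``; dialect
    "genalex": GenAlEx export (two meta rows, then ``Sample,Pop,<locus>,,...``
    with two unnamed-second columns per locus).

    Unparseable allele tokens and the configured sentinel codes map to
    missing; a half-missing pair is treated as fully missing.
    """
    missing_codes = set(int(c) for c in missing_codes)
    if dialect == "wide":
        df = pd.read_csv(path, dtype=str)
        if df.columns[0].lower() != "id":
            raise ValueError("wide dialect requires first column 'id'")
        allele_cols = list(df.columns[1:])
        if len(allele_cols) % 2:
            raise ValueError("odd number of allele columns (ragged header)")
        loci = []
        for c1, c2 in zip(allele_cols[::2], allele_cols[1::2]):
            if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
                raise ValueError(f"columns {c1!r},{c2!r} are not a <locus>_1/<locus>_2 pair")
            loci.append(c1[:-2])
        if df[allele_cols].isna().any(axis=1).any():
            bad = df.index[df[allele_cols].isna().any(axis=1)][0]
            raise ValueError(f"ragged row at index {bad} (id={df.iloc[bad, 0]!r})")
        ids = df.iloc[:, 0].tolist()
        raw = df[allele_cols].map(lambda t: _parse_allele(t, missing_codes))
        calls = raw.to_numpy(dtype=np.int64).reshape(len(ids), len(loci), 2)
        return GenotypeTable(ids, loci, calls)
    elif dialect == "genalex":
        import csv
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if len(rows) < 4:
            raise ValueError("GenAlEx file too short (2 meta rows + header + data)")
        header = rows[2]
        loci = [h for h in header[2::2] if h.strip()]
        need = 2 + 2 * len(loci)
        ids, calls = [], []
        for r in rows[3:]:
            if not any(f.strip() for f in r):
                continue
            if len(r) < need:
                raise ValueError(f"ragged row for individual {r[0]!r}")
            ids.append(r[0])
            calls.append([_parse_allele(t, missing_codes) for t in r[2:need]])
        calls = np.array(calls, dtype=np.int64).reshape(len(ids), len(loci), 2)
        return GenotypeTable(ids, loci, calls)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_passport_table(path) -> pd.DataFrame:
    """Read a passport CSV with columns id, lon, lat[, covariates...]."""
    df = pd.read_csv(path)
    required = {"id", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(f"passport table must have columns {sorted(required)}")
    df["id"] = df["id"].astype(str)
    return df


def _rjack_pass(x_all: np.ndarray) -> np.ndarray:
    """One screening pass of the Chapman (2005) reverse-jackknife statistic.

    Sort the distinct values x(1)..x(m); for each adjacent gap form the
    product of the gap with the distance of the outer value from the mean,

        y_i = (x(i+1) - x(i)) * (mean - x(i))     if x(i) <  mean
        y_i = (x(i+1) - x(i)) * (x(i+1) - mean)   if x(i) >= mean

    standardise y by its standard deviation, and flag every observation at
    or beyond a gap whose standardised value exceeds the critical value
    c = 0.95*sqrt(n) + 0.2. Returns a boolean flag mask.
    """
    n = x_all.size
    flagged = np.zeros(n, dtype=bool)
    x = np.unique(x_all)
    if x.size < 3 or x.max() == x.min():
        return flagged
    mx = x.mean()
    gaps = np.diff(x)
    lo = x[:-1] < mx
    y = np.where(lo, gaps * (mx - x[:-1]), gaps * (x[1:] - mx))
    sd = np.sqrt(np.sum((y - y.mean()) ** 2) / y.size)
    if sd == 0:
        return flagged
    z = y / sd
    crit = 0.95 * np.sqrt(n) + 0.2
    big = np.nonzero(z > crit)[0]
    if big.size == 0:
        return flagged
    med = np.median(x)
    v = x[big]
    if (v < med).any():
        # everything at or below the lower edge of the lowest flagged gap
        flagged |= x_all <= x[big[v < med].min()]
    if (v > med).any():
        # everything at or above the upper edge of the highest flagged gap
        flagged |= x_all >= x[big[v > med].max() + 1]
    return flagged


def reverse_jackknife_outliers(values) -> set:
    """Flag extreme values by the reverse jackknife (Chapman 2005 gap test).

    The climatic-outlier screen popularised by DIVA-GIS. The single-pass gap
    statistic (see :func:`_rjack_pass`) standardises each inter-value gap by
    the spread of all gaps, so simultaneous outliers in both tails mask one
    another; the pass is therefore repeated on the retained values until no
    further flags arise, which treats the two tails symmetrically.
    Deterministic; returns indices into the input vector.
    """
    x_all = np.asarray(values, dtype=float)
    n = x_all.size
    if n < 3:
        warnings.warn("reverse jackknife needs at least 3 values; nothing flagged")
        return set()
    if not np.isfinite(x_all).all():
        raise ValueError("values must be finite")
    flagged = np.zeros(n, dtype=bool)
    while True:
        active = np.nonzero(~flagged)[0]
        if active.size < 3:
            break
        new = _rjack_pass(x_all[active])
        if not new.any():
            break
        flagged[active[new]] = True
    return set(np.nonzero(flagged)[0].tolist())


def clean_dataset(genotypes: GenotypeTable, passports: pd.DataFrame,
                  covariates=None, iterative: bool = False):
    """Drop individuals without coordinates, then covariate outliers.

    ``covariates``: column names in ``passports`` to screen with
    :func:`reverse_jackknife_outliers` (default: every numeric column other
    than lon/lat). Single-pass per column with the flagged union removed;
    ``iterative=True`` repeats until no new flags. Returns the cleaned
    genotype table, the matching passports and a :class:`CleaningReport`.
    """
    pp = passports.copy()
    pp["id"] = pp["id"].astype(str)
    shared = [i for i in genotypes.ids if i in set(pp["id"])]
    if not shared:
        raise ValueError("genotype and passport tables share no individual ids")
    pp = pp.set_index("id").loc[shared].reset_index()
    n_input = len(shared)
    removed: dict[str, str] = {}

    has_coords = pp["lon"].notna() & pp["lat"].notna()
    for i in pp.loc[~has_coords, "id"]:
        removed[i] = "missing coordinates"
    pp = pp[has_coords].reset_index(drop=True)

    if covariates is None:
        covariates = [c for c in pp.columns
                      if c not in ("id", "lon", "lat")
                      and pd.api.types.is_numeric_dtype(pp[c])]
    n_outliers = 0
    while True:
        flagged_ids: set[str] = set()
        for col in covariates:
            vals = pp[col].to_numpy(dtype=float)
            for idx in reverse_jackknife_outliers(vals):
                flagged_ids.add(pp["id"].iloc[idx])
        if not flagged_ids:
            break
        for i in sorted(flagged_ids):
            removed[i] = "covariate outlier (reverse jackknife)"
        n_outliers += len(flagged_ids)
        pp = pp[~pp["id"].isin(flagged_ids)].reset_index(drop=True)
        if not iterative:
            break

    kept = pp["id"].tolist()
    report = CleaningReport(
        n_input=n_input,
        n_retained=len(kept),
        n_removed_missing_coords=sum(1 for r in removed.values()
                                     if r == "missing coordinates"),
        n_removed_outliers=n_outliers,
        removed_ids=removed,
    )
    return genotypes.subset(kept), pp, report
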