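"""Genetic cluster discovery and characterisation.

k-means on PCA-transformed allele frequencies with a BIC scan picks the
number of groups; a discriminant analysis of principal components (DAPC)
turns the hard labels into per-individual membership probabilities; clusters
are then compared by Nei's (1972) standard genetic distance, summarised in a
complete-linkage dendrogram, and tested for isolation by distance with a
Mantel permutation test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .diversity import AlleleCountSpectrum, allele_counts
from .io import GenotypeTable

log = logging.getLogger(__name__)


@dataclass
class AlleleMatrix:
    """Individuals x allele-columns relative dosages (0 / 0.5 / 1).

    One column per observed allele; a heterozygote contributes 0.5 to each of
    its two allele columns, a homozygote 1. Missing genotypes are imputed
    with the column mean of scored individuals, so complete rows sum to 1
    within each locus.
    """

    ids: list
    X: np.ndarray            # (n, p) float
    col_locus: np.ndarray    # (p,) locus name per column
    col_allele: np.ndarray   # (p,) allele label per column


def build_allele_matrix(genotypes: GenotypeTable) -> AlleleMatrix:
    if genotypes.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    enc = genotypes.encoded()
    n, L, _ = enc.codes.shape
    blocks, loci_cols, allele_cols = [], [], []
    for l in range(L):
        lab = enc.labels[l]
        if lab.size == 0:
            continue
        block = np.zeros((n, lab.size))
        for s in (0, 1):
            c = enc.codes[:, l, s]
            ok = c >= 0
            block[np.nonzero(ok)[0], c[ok]] += 0.5
        scored = enc.codes[:, l, 0] >= 0
        if scored.any() and not scored.all():
            block[~scored] = block[scored].mean(axis=0)
        blocks.append(block)
        loci_cols.extend([genotypes.loci[l]] * lab.size)
        allele_cols.extend(lab.tolist())
    X = np.hstack(blocks)
    return AlleleMatrix(ids=list(genotypes.ids), X=X,
                        col_locus=np.array(loci_cols), col_allele=np.array(allele_cols))


def _pca_scores(X: np.ndarray, n_pcs=None, var_target: float = 0.95):
    """Centered PCA scores; zero-variance columns dropped with a log note."""
    keep = X.std(axis=0) > 0
    if not keep.all():
        log.info("dropping %d zero-variance allele columns before PCA", int((~keep).sum()))
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    full = PCA(svd_solver="full").fit(Xc)
    if n_pcs is None:
        cum = np.cumsum(full.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, var_target) + 1)
    n_pcs = min(n_pcs, full.n_components_)
    return Xc @ full.components_[:n_pcs].T, n_pcs


@dataclass
class BICCurve:
    ks: np.ndarray
    bic: np.ndarray
    chosen_k: int
    n_pcs: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "bic": self.bic})


def kmeans_bic_scan(matrix: AlleleMatrix, k_range=range(1, 21), n_pcs=None,
                    n_starts: int = 5, seed: int = 0) -> BICCurve:
    """Scan k-means solutions over PCA scores and score them with BIC.

    BIC(k) = n*ln(WSS_k/n) + k*ln(n) on the retained PC scores. ``chosen_k``
    is the elbow suggestion — the k with the largest positive second
    difference of the curve — and is meant as a suggestion: the final k is
    the analyst's call.
    """
    scores, n_pcs = _pca_scores(matrix.X, n_pcs)
    n = scores.shape[0]
    ks, bics = [], []
    for k in k_range:
        if k >= n:
            continue
        if k == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed).fit(scores)
            wss = float(km.inertia_)
        ks.append(k)
        bics.append(n * np.log(wss / n) + k * np.log(n))
    ks, bics = np.array(ks), np.array(bics)
    if len(ks) >= 3:
        second = bics[:-2] - 2 * bics[1:-1] + bics[2:]
        chosen = int(ks[1 + int(np.argmax(second))])
    else:
        chosen = int(ks[int(np.argmin(bics))])
    return BICCurve(ks=ks, bic=bics, chosen_k=chosen, n_pcs=n_pcs)


@dataclass
class ClusterModel:
    k: int
    ids: list
    labels: np.ndarray       # (n,) int, argmax of membership
    membership: np.ndarray   # (n, k) row-stochastic

    def membership_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.membership, index=self.ids,
                            columns=[f"cluster_{j}" for j in range(self.k)])


def fit_kmeans(matrix: AlleleMatrix, k: int, n_pcs=None, n_starts: int = 5,
               seed: int = 0) -> np.ndarray:
    """Hard k-means labels on PCA scores (the clusters DAPC then describes)."""
    scores, _ = _pca_scores(matrix.X, n_pcs)
    return KMeans(n_clusters=k, n_init=n_starts, random_state=seed).fit_predict(scores)


def dapc_membership(matrix: AlleleMatrix, labels, n_pcs=None, n_da=None) -> ClusterModel:
    """DAPC-style membership probabilities for predefined clusters.

    PCA retention followed by linear discriminant analysis; memberships are
    Gaussian posteriors with shared within-group covariance (identity in the
    whitened discriminant space) and uniform priors.
    """
    labels = np.asarray(labels)
    uniq, labels_idx = np.unique(labels, return_inverse=True)
    k = uniq.size
    if np.bincount(labels_idx).min() < 2:
        raise ValueError("every cluster needs at least 2 members")
    scores, _ = _pca_scores(matrix.X, n_pcs)
    if n_da is None:
        n_da = k - 1
    n_da = max(1, min(n_da, k - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear PCs are harmless here
        lda = LinearDiscriminantAnalysis(priors=np.full(k, 1.0 / k))
        lda.fit(scores, labels_idx)
        Z = lda.transform(scores)[:, :n_da]
    centroids = np.vstack([Z[labels_idx == j].mean(axis=0) for j in range(k)])
    d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    logpost = -0.5 * d2
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    return ClusterModel(k=k, ids=list(matrix.ids),
                        labels=post.argmax(axis=1), membership=post)


def cluster_spectra(genotypes: GenotypeTable, model: ClusterModel,
                    min_membership: float = 0.7) -> dict:
    """Per-cluster allele count spectra from confidently assigned members.

    Only individuals whose membership for their best cluster is at least
    ``min_membership`` (inclusive) contribute. Emptied clusters are dropped
    with a warning.
    """
    best = model.membership.max(axis=1)
    out = {}
    for j in range(model.k):
        members = [model.ids[i] for i in range(len(model.ids))
                   if model.labels[i] == j and best[i] >= min_membership]
        if not members:
            warnings.warn(f"cluster {j} emptied by membership threshold {min_membership}")
            continue
        out[j] = allele_counts(genotypes, members)
    return out


def cluster_members(model: ClusterModel, min_membership: float = 0.7) -> dict:
    """Cluster -> confidently assigned individual ids (same rule as spectra)."""
    best = model.membership.max(axis=1)
    return {j: [model.ids[i] for i in range(len(model.ids))
                if model.labels[i] == j and best[i] >= min_membership]
            for j in range(model.k)}


def nei_distance_matrix(spectra_by_cluster: dict):
    """Nei (1972) standard genetic distance between cluster allele spectra.

    D = -ln( J_xy / sqrt(J_x * J_y) ) with the identity sums J pooled over
    loci and alleles. D >= 0 with equality iff the spectra coincide; it is
    not a metric (the triangle inequality can fail). Disjoint allele sets
    give J_xy = 0 and D = +inf, reported with a warning.
    """
    names = list(spectra_by_cluster)
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    freqs = {}
    for u in names:
        spec = spectra_by_cluster[u]
        freqs[u] = [spec.frequencies(l) for l in range(len(spec.loci))]
    D = np.zeros((len(names), len(names)))
    for a, b in itertools.combinations(range(len(names)), 2):
        jxy = jx = jy = 0.0
        for fx, fy in zip(freqs[names[a]], freqs[names[b]]):
            jx += sum(v * v for v in fx.values())
            jy += sum(v * v for v in fy.values())
            jxy += sum(v * fy.get(al, 0.0) for al, v in fx.items())
        if jxy == 0:
            warnings.warn(f"clusters {names[a]} and {names[b]} share no alleles: D = inf")
            D[a, b] = D[b, a] = np.inf
        else:
            D[a, b] = D[b, a] = -np.log(jxy / np.sqrt(jx * jy))
    return names, D


def _linkage_to_newick(Z: np.ndarray, names) -> str:
    """Ultrametric Newick from a scipy linkage matrix (leaf depth = height/2)."""
    n = len(names)
    height = {i: 0.0 for i in range(n)}
    node = {i: str(names[i]) for i in range(n)}
    for j, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        h2 = h / 2.0
        node[n + j] = (f"({node[a]}:{h2 - height[a]:.6g},"
                       f"{node[b]}:{h2 - height[b]:.6g})")
        height[n + j] = h2
    return node[n + len(Z) - 1] + ";"


def complete_linkage_tree(D: np.ndarray, names=None):
    """Complete-linkage dendrogram and its cophenetic correlation.

    Returns ``(newick, cophenetic_r, linkage_matrix)``. The cophenetic r —
    the Pearson correlation between input and ultrametric tree distances —
    measures how faithfully the dendrogram represents the distance matrix.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if names is None:
        names = list(range(n))
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    if n >= 3:
        coph_r, _ = hierarchy.cophenet(Z, squareform(D, checks=False))
        coph_r = float(coph_r)
    else:
        coph_r = float("nan")
    return _linkage_to_newick(Z, names), coph_r, Z


def _triu(D: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(D.shape[0], k=1)
    return D[i, j]


def mantel_test(D1, D2, n_perm: int = 999, seed: int = 0, exact: bool = False):
    """One-sided Mantel test of matrix association.

    r is the Pearson correlation of the off-diagonal upper triangles;
    significance comes from random (or, with ``exact=True``, all n!)
    row/column permutations of D2, with p = (1 + #{r_perm >= r_obs}) /
    (1 + n_perm). Matrices must share label order.
    """
    D1, D2 = np.asarray(D1, float), np.asarray(D2, float)
    n = D1.shape[0]
    if D1.shape != D2.shape or n < 4:
        raise ValueError("need two equally sized matrices with n >= 4")
    x = _triu(D1)
    if np.std(x) == 0 or np.std(_triu(D2)) == 0:
        raise ValueError("constant distance matrix")
    x = (x - x.mean()) / x.std()

    def corr(Dp):
        y = _triu(Dp)
        y = (y - y.mean()) / y.std()
        return float((x * y).mean())

    r_obs = corr(D2)
    if exact:
        perms = itertools.permutations(range(n))
        count = total = 0
        for p in perms:
            p = np.array(p)
            if corr(D2[np.ix_(p, p)]) >= r_obs - 1e-12:
                count += 1
            total += 1
        # identity permutation is the observed value itself
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr(D2[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


def individual_nei_distance(genotypes: GenotypeTable, ids=None) -> np.ndarray:
    """Nei (1972) distance between individuals, each treated as a 2-copy population."""
    if ids is None:
        ids = genotypes.ids
    spectra = {i: allele_counts(genotypes, [i]) for i in ids}
    _, D = nei_distance_matrix(spectra)
    return D
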