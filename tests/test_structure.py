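import math

import numpy as np
import pytest

from divgrid import (GenotypeTable, allele_counts, build_allele_matrix,
                     cluster_spectra, complete_linkage_tree, dapc_membership,
                     fit_kmeans, kmeans_bic_scan, mantel_test,
                     nei_distance_matrix)
from divgrid.diversity import AlleleCountSpectrum
from divgrid.structure import AlleleMatrix, ClusterModel

from conftest import small_dataset


class TestAlleleMatrix:
    def test_dosage_encoding(self, tiny_table):
        m = build_allele_matrix(tiny_table)
        col = {(l, a): j for j, (l, a) in enumerate(zip(m.col_locus, m.col_allele))}
        assert m.X[1, col[("L1", 152)]] == 1.0          # homozygote
        assert m.X[0, col[("L1", 152)]] == 0.5          # heterozygote
        assert m.X[0, col[("L1", 158)]] == 0.5

    def test_rows_sum_to_one_within_each_locus(self, tiny_table):
        m = build_allele_matrix(tiny_table)
        for locus in tiny_table.loci:
            block = m.X[:, m.col_locus == locus]
            np.testing.assert_allclose(block.sum(axis=1), 1.0, atol=1e-9)

    def test_missing_imputed_with_column_mean(self, tiny_table):
        m = build_allele_matrix(tiny_table)
        block = m.X[:, m.col_locus == "L3"]
        scored = [0, 1, 2, 4, 5]
        np.testing.assert_allclose(block[3], block[scored].mean(axis=0))


def _planted_blobs(k=3, n=40, d=30, sep=12.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 1, (k, d)) * sep / math.sqrt(d)
    X = np.vstack([centers[j] + rng.normal(0, 1, (n, d)) for j in range(k)])
    labels = np.repeat(np.arange(k), n)
    ids = [f"i{t}" for t in range(k * n)]
    m = AlleleMatrix(ids=ids, X=X, col_locus=np.array(["L"] * d),
                     col_allele=np.arange(d))
    return m, labels


class TestKmeansBic:
    def test_recovers_planted_k(self):
        m, _ = _planted_blobs(k=3, seed=1)
        curve = kmeans_bic_scan(m, k_range=range(1, 9), seed=0)
        assert curve.chosen_k == 3

    def test_invariant_to_row_duplication(self, small_scenario):
        gt, _, _, _ = small_scenario
        m = build_allele_matrix(gt)
        c1 = kmeans_bic_scan(m, range(1, 8), seed=0)
        dup = GenotypeTable([i + "a" for i in gt.ids] + [i + "b" for i in gt.ids],
                            gt.loci, np.vstack([gt.calls, gt.calls]))
        c2 = kmeans_bic_scan(build_allele_matrix(dup), range(1, 8), seed=0)
        assert c1.chosen_k == c2.chosen_k

    def test_k1_bic_closed_form(self):
        m, _ = _planted_blobs(k=1, n=50, seed=2)
        curve = kmeans_bic_scan(m, k_range=[1], n_pcs=5, seed=0)
        from divgrid.structure import _pca_scores
        scores, _ = _pca_scores(m.X, 5)
        n = scores.shape[0]
        wss = ((scores - scores.mean(axis=0)) ** 2).sum()
        assert curve.bic[0] == pytest.approx(n * np.log(wss / n) + np.log(n))


class TestDapcMembership:
    def test_separated_clusters_get_confident_memberships(self):
        m, labels = _planted_blobs(k=2, sep=20.0, seed=3)
        model = dapc_membership(m, labels)
        own = model.membership[np.arange(len(labels)), labels]
        assert (own > 0.99).all()
        assert (model.labels == labels).all()

    def test_rows_sum_to_one(self):
        m, labels = _planted_blobs(k=3, sep=3.0, seed=4)
        model = dapc_membership(m, labels)
        np.testing.assert_allclose(model.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_exact_midpoint_is_half_half(self):
        # two mirror-image clusters, each holding one copy of the midpoint,
        # keep the training set perfectly symmetric about the origin
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.5, (30, 4)) + 5
        X = np.vstack([a, -a, np.zeros((2, 4))])
        m = AlleleMatrix(ids=[str(i) for i in range(62)], X=X,
                         col_locus=np.array(["L"] * 4), col_allele=np.arange(4))
        labels = np.array([0] * 30 + [1] * 30 + [0, 1])
        model = dapc_membership(m, labels, n_pcs=4)
        np.testing.assert_allclose(model.membership[-1], [0.5, 0.5], atol=1e-6)
        np.testing.assert_allclose(model.membership[-2], [0.5, 0.5], atol=1e-6)

    def test_recovers_planted_populations(self, small_scenario):
        from sklearn.metrics import adjusted_rand_score
        gt, _, truth, _ = small_scenario
        m = build_allele_matrix(gt)
        labels = fit_kmeans(m, 3, seed=0)
        model = dapc_membership(m, labels)
        assert adjusted_rand_score(truth.pop, model.labels) >= 0.9


class TestClusterSpectra:
    def _model(self, gt, membership):
        membership = np.asarray(membership, dtype=float)
        return ClusterModel(k=membership.shape[1], ids=list(gt.ids),
                            labels=membership.argmax(axis=1), membership=membership)

    def test_no_filtering_at_full_confidence(self, tiny_table):
        mem = np.zeros((6, 2))
        mem[:3, 0] = 1.0
        mem[3:, 1] = 1.0
        spectra = cluster_spectra(tiny_table, self._model(tiny_table, mem))
        assert spectra[0].counts == allele_counts(tiny_table, tiny_table.ids[:3]).counts
        assert spectra[1].counts == allele_counts(tiny_table, tiny_table.ids[3:]).counts

    def test_membership_exactly_at_threshold_is_retained(self, tiny_table):
        mem = np.tile([0.7, 0.3], (6, 1))
        spectra = cluster_spectra(tiny_table, self._model(tiny_table, mem),
                                  min_membership=0.7)
        assert 0 in spectra

    def test_below_threshold_is_dropped(self, tiny_table):
        mem = np.tile([0.65, 0.35], (6, 1))
        with pytest.warns(UserWarning, match="emptied"):
            spectra = cluster_spectra(tiny_table, self._model(tiny_table, mem),
                                      min_membership=0.7)
        assert spectra == {}


def spectrum(*counts):
    return AlleleCountSpectrum(loci=[f"L{i}" for i in range(len(counts))],
                               counts=list(counts))


class TestNeiDistance:
    def test_identical_spectra_distance_zero(self):
        a = spectrum({1: 4, 2: 4}, {1: 8})
        names, D = nei_distance_matrix({"A": a, "B": a})
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_single_locus_worked_example(self):
        a = spectrum({1: 10})            # frequencies (1, 0)
        b = spectrum({1: 5, 2: 5})       # frequencies (0.5, 0.5)
        _, D = nei_distance_matrix({"A": a, "B": b})
        assert D[0, 1] == pytest.approx(-math.log(0.5 / math.sqrt(0.5)), abs=1e-9)
        assert D[0, 1] == pytest.approx(0.3466, abs=2e-4)

    def test_symmetric_and_nonnegative_on_random_spectra(self):
        rng = np.random.default_rng(8)
        groups = {}
        for name in "ABCD":
            groups[name] = spectrum(*[
                {int(a): int(c) for a, c in
                 enumerate(rng.integers(1, 10, size=rng.integers(2, 6)))}
                for _ in range(5)])
        _, D = nei_distance_matrix(groups)
        np.testing.assert_allclose(D, D.T)
        assert (D >= 0).all() and np.allclose(np.diag(D), 0)

    def test_disjoint_spectra_are_infinitely_distant(self):
        a, b = spectrum({1: 4}), spectrum({2: 4})
        with pytest.warns(UserWarning, match="inf"):
            _, D = nei_distance_matrix({"A": a, "B": b})
        assert np.isinf(D[0, 1])


class TestCompleteLinkage:
    def test_hand_agglomeration_three_points(self):
        D = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        newick, coph, Z = complete_linkage_tree(D, names=list("abc"))
        assert Z[0][2] == pytest.approx(1.0)   # (a,b) merge first at height 1
        assert Z[1][2] == pytest.approx(5.0)   # then c joins at 5
        assert newick.endswith(";") and "a" in newick and "c" in newick

    def test_ultrametric_input_gives_perfect_cophenetic(self):
        # distances from an ultrametric tree: ((a,b):3,(c,d):2):6
        D = np.array([[0, 3, 6, 6], [3, 0, 6, 6],
                      [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float)
        _, coph, _ = complete_linkage_tree(D)
        assert coph == pytest.approx(1.0)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        _, _, Z = complete_linkage_tree(D)
        heights = Z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestMantel:
    @staticmethod
    def _dist(x):
        return np.abs(x[:, None] - x[None, :])

    def test_self_comparison_r_one_minimal_p(self):
        rng = np.random.default_rng(0)
        D = self._dist(rng.normal(size=20))
        r, p = mantel_test(D, D, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_exact_enumeration_matches_skbio_oracle(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(4)
        D1 = self._dist(rng.normal(size=5))
        D2 = self._dist(rng.normal(size=5))
        r_me, p_me = mantel_test(D1, D2, exact=True)
        r_sk, p_sk, _ = skbio_mantel(DistanceMatrix(D1), DistanceMatrix(D2),
                                     permutations=50_000, alternative="greater")
        assert r_me == pytest.approx(r_sk, abs=1e-9)
        assert p_me == pytest.approx(p_sk, abs=0.02)  # MC oracle vs exact null

    def test_monte_carlo_converges_to_exact_p(self):
        rng = np.random.default_rng(6)
        D1 = self._dist(rng.normal(size=5))
        D2 = self._dist(rng.normal(size=5))
        _, p_exact = mantel_test(D1, D2, exact=True)
        _, p_mc = mantel_test(D1, D2, n_perm=20_000, seed=2)
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_constant_matrix_is_an_error(self):
        D = np.ones((6, 6)) - np.eye(6)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(D, D * 0, n_perm=99)
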