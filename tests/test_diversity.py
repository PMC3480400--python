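import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divgrid import (GenotypeTable, allele_counts, allelic_richness,
                     locally_common_alleles, nei_gene_diversity,
                     observed_heterozygosity, private_alleles,
                     rarefaction_expected_alleles, shannon_index)
from divgrid.diversity import (AlleleCountSpectrum,
                               rarefaction_expected_alleles_locus)


def spectrum(*counts_per_locus):
    return AlleleCountSpectrum(loci=[f"L{i}" for i in range(len(counts_per_locus))],
                               counts=list(counts_per_locus))


class TestAlleleCounts:
    def test_heterozygote_contributes_one_copy_per_allele(self, tiny_table):
        s = allele_counts(tiny_table, ["i0"])
        assert s.counts[0] == {152: 1, 158: 1}
        assert s.n_copies[0] == 2

    def test_copy_counting_over_individuals(self, tiny_table):
        s = allele_counts(tiny_table, ["i0", "i1"])
        assert s.counts[0] == {152: 3, 158: 1}
        assert s.n_copies[0] == 4

    def test_missing_pair_contributes_nothing(self, tiny_table):
        with_miss = allele_counts(tiny_table, ["i0", "i3"])
        without = allele_counts(tiny_table, ["i0"])
        assert with_miss.counts[2] == without.counts[2]  # i3 missing at L3


class TestClosedForms:
    def test_monomorphic_loci(self):
        s = spectrum({1: 10}, {5: 4})
        assert allelic_richness(s) == 1.0
        assert nei_gene_diversity(s) == 0.0
        assert shannon_index(s) == 0.0

    def test_richness_is_mean_over_loci(self):
        s = spectrum({1: 1, 2: 1, 3: 1}, {1: 1, 2: 1, 3: 1, 4: 1, 5: 1})
        assert allelic_richness(s) == 4.0

    def test_nei_two_equifrequent_alleles(self):
        assert nei_gene_diversity(spectrum({1: 5, 2: 5})) == pytest.approx(0.5)

    def test_nei_four_equifrequent_alleles(self):
        assert nei_gene_diversity(spectrum({1: 4, 2: 4, 3: 4, 4: 4})) == pytest.approx(0.75)

    def test_shannon_uniform_is_log_k(self):
        assert shannon_index(spectrum({1: 3, 2: 3})) == pytest.approx(math.log(2))
        for k in (3, 5, 8):
            s = spectrum({a: 2 for a in range(k)})
            assert shannon_index(s) == pytest.approx(math.log(k))

    def test_nei_bounded_by_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(1, 10)
            s = spectrum({a: int(c) for a, c in
                          enumerate(rng.integers(1, 20, size=k))})
            nei = nei_gene_diversity(s)
            assert 0.0 <= nei <= 1.0 - 1.0 / k + 1e-12
            assert shannon_index(s) >= 0.0

    def test_richness_matches_set_cardinality_oracle(self):
        rng = np.random.default_rng(1)
        counts = [{int(a): int(c) for a, c in
                   enumerate(rng.integers(1, 9, size=rng.integers(1, 12)))}
                  for _ in range(10)]
        s = AlleleCountSpectrum(loci=[f"L{i}" for i in range(10)], counts=counts)
        assert allelic_richness(s) == pytest.approx(
            np.mean([len(set(c)) for c in counts]))


class TestObservedHeterozygosity:
    def test_all_homozygotes(self):
        calls = np.tile(np.array([[5, 5]]), (4, 2, 1)).reshape(4, 2, 2)
        t = GenotypeTable(list("abcd"), ["L1", "L2"], calls)
        assert observed_heterozygosity(t) == 0.0

    def test_all_heterozygotes(self):
        calls = np.tile(np.array([[5, 7]]), (4, 2, 1)).reshape(4, 2, 2)
        t = GenotypeTable(list("abcd"), ["L1", "L2"], calls)
        assert observed_heterozygosity(t) == 1.0

    def test_hwe_expectation_half(self):
        rng = np.random.default_rng(11)
        n = 10_000
        calls = rng.choice([1, 2], size=(n, 1, 2))
        t = GenotypeTable([str(i) for i in range(n)], ["L"], calls)
        assert observed_heterozygosity(t) == pytest.approx(0.5, abs=0.015)


class TestRarefaction:
    def test_census_sample_returns_exact_count(self):
        assert rarefaction_expected_alleles_locus({1: 1, 2: 15}, 16) == pytest.approx(2.0)
        assert rarefaction_expected_alleles_locus({1: 3, 2: 4, 3: 5}, 12) == pytest.approx(3.0)

    def test_two_alleles_g2_closed_form(self):
        expected = 2 * (1 - 28 / 120)  # 1 - C(8,2)/C(16,2) per allele
        assert rarefaction_expected_alleles_locus({1: 8, 2: 8}, 2) == pytest.approx(expected)

    @pytest.mark.parametrize("counts,g", [
        ({1: 8, 2: 8}, 2),
        ({1: 3, 2: 5, 3: 2}, 4),
        ({1: 1, 2: 1, 3: 10}, 6),
        ({1: 7, 2: 2, 3: 2, 4: 1}, 8),
    ])
    def test_matches_exhaustive_enumeration(self, counts, g):
        copies = [a for a, c in counts.items() for _ in range(c)]
        brute = np.mean([len(set(sub))
                         for sub in itertools.combinations(copies, g)])
        assert rarefaction_expected_alleles_locus(counts, g) == pytest.approx(brute)

    def test_monotone_in_g(self):
        counts = {1: 9, 2: 4, 3: 2, 4: 1}
        vals = [rarefaction_expected_alleles_locus(counts, g) for g in range(1, 17)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_underfilled_loci_are_excluded_with_warning(self):
        s = spectrum({1: 8, 2: 8}, {1: 2})
        with pytest.warns(UserWarning, match="excluded"):
            v = rarefaction_expected_alleles(s, 16)
        assert v == pytest.approx(2 * (1 - 0))  # only the 16-copy locus counts

    def test_invalid_g(self):
        with pytest.raises(ValueError):
            rarefaction_expected_alleles_locus({1: 4}, 0)


class TestPrivateAlleles:
    def test_identical_groups_have_none(self):
        a = spectrum({1: 4, 2: 4})
        assert private_alleles({"A": a, "B": a}) == {"A": 0.0, "B": 0.0}

    def test_single_private_allele_count(self):
        n_loci = 96
        base = [{1: 4} for _ in range(n_loci)]
        withx = [dict(c) for c in base]
        withx[0][999] = 1
        groups = {"A": AlleleCountSpectrum([str(i) for i in range(n_loci)], withx),
                  "B": AlleleCountSpectrum([str(i) for i in range(n_loci)], base)}
        out = private_alleles(groups)
        assert out["A"] == pytest.approx(1 / 96)
        assert out["B"] == 0.0

    def test_matches_set_difference_oracle(self):
        rng = np.random.default_rng(5)
        groups = {}
        for name in "ABC":
            counts = [{int(a): 1 for a in rng.choice(12, size=rng.integers(1, 8),
                                                     replace=False)}
                      for _ in range(6)]
            groups[name] = AlleleCountSpectrum([f"L{i}" for i in range(6)], counts)
        out = private_alleles(groups)
        for name in "ABC":
            brute = 0
            for l in range(6):
                others = set().union(*(set(groups[o].counts[l])
                                       for o in "ABC" if o != name))
                brute += len(set(groups[name].counts[l]) - others)
            assert out[name] == pytest.approx(brute / 6)


class TestLocallyCommonAlleles:
    def test_rare_but_frequent_allele_counts_inclusively(self):
        # allele 9 in 1 of 4 cells (25% <= 25%) at frequency 0.10 (>= 5%)
        cells = {"c1": spectrum({1: 18, 9: 2}),
                 "c2": spectrum({1: 20}), "c3": spectrum({1: 20}),
                 "c4": spectrum({1: 20})}
        out = locally_common_alleles(cells, occupancy_max_frac=0.25, freq_min=0.05)
        assert out["c1"] == 1.0
        assert out["c2"] == 0.0

    def test_ubiquitous_allele_never_counts(self):
        cells = {f"c{i}": spectrum({1: 10, 2: 10}) for i in range(4)}
        out = locally_common_alleles(cells, occupancy_max_frac=0.25, freq_min=0.05)
        assert all(v == 0.0 for v in out.values())

    def test_cluster_mode_frequency_is_strict(self):
        # allele 9 in 2 of 10 clusters at frequency exactly 0.05: NOT counted
        cells = {f"k{i}": spectrum({1: 20}) for i in range(8)}
        cells["k8"] = spectrum({1: 19, 9: 1})  # freq 0.05 exactly
        cells["k9"] = spectrum({1: 19, 9: 1})
        out = locally_common_alleles(cells, occupancy_max_units=2,
                                     freq_min=0.05, strict=True)
        assert all(v == 0.0 for v in out.values())
        relaxed = locally_common_alleles(cells, occupancy_max_units=2,
                                         freq_min=0.05, strict=False)
        assert relaxed["k8"] == 1.0

    def test_single_unit_warns(self):
        with pytest.warns(UserWarning, match="single unit"):
            locally_common_alleles({"c": spectrum({1: 10})},
                                   occupancy_max_frac=0.25)


@settings(deadline=None, max_examples=25)
@given(st.lists(st.tuples(st.integers(1, 6), st.integers(1, 6)),
                min_size=2, max_size=30),
       st.integers(0, 2**31 - 1))
def test_statistics_invariant_to_relabeling_and_order(genos, seed):
    """Richness/Nei/Shannon are label-free and order-free by construction."""
    calls = np.array([[[a * 2, b * 2]] for a, b in genos])
    t = GenotypeTable([f"i{k}" for k in range(len(genos))], ["L"], calls)
    rng = np.random.default_rng(seed)
    relabel = {v: i + 100 for i, v in enumerate(rng.permutation(np.arange(2, 13, 2)))}
    calls2 = np.vectorize(lambda x: relabel[x])(calls)
    order = rng.permutation(len(genos))
    t2 = GenotypeTable([f"i{k}" for k in order], ["L"], calls2[order])
    for fn in (allelic_richness, nei_gene_diversity, shannon_index):
        assert fn(allele_counts(t)) == pytest.approx(fn(allele_counts(t2)))
    assert observed_heterozygosity(t) == pytest.approx(observed_heterozygosity(t2))
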