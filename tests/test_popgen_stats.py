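import itertools
import math

import numpy as np
import pytest

from conftest import small_table
from clutchkin.genodata import make_genotype_table
from clutchkin.popgen_stats import (
    AlleleFrequencies,
    allele_frequencies,
    exclusion_probability,
    haplotype_diversity,
    heterozygosities,
    hwe_exact_test,
)


def adults(genos, loci=("L1",)):
    recs = []
    for i, g in enumerate(genos):
        recs.append((f"A{i}", None, 2019, "adult", {loci[j]: g[j] for j in range(len(loci))}))
    return make_genotype_table(recs, loci)


class TestAlleleFrequencies:
    def test_gene_copy_counting(self):
        gt = adults([[(1, 1)], [(1, 2)]])
        fr = allele_frequencies(gt)
        assert fr.of("L1") == {1: 0.75, 2: 0.25}
        assert fr.n_copies["L1"] == 4

    def test_all_missing_locus_flagged_empty(self):
        gt = adults([[None], [None]])
        fr = allele_frequencies(gt)
        assert fr.of("L1") == {}
        assert "L1" in fr.flagged_empty

    def test_estimates_within_three_se_of_truth(self):
        rng = np.random.default_rng(0)
        p_true = 0.3
        n = 400
        draws = rng.random((n, 2)) < p_true
        gt = adults([[(1, 2) if a != b else ((1, 1) if a else (2, 2))] for a, b in draws])
        fr = allele_frequencies(gt)
        se = math.sqrt(p_true * (1 - p_true) / (2 * n))
        assert abs(fr.of("L1")[1] - p_true) < 3 * se

    def test_empty_subset_rejected(self):
        gt = adults([[(1, 2)]])
        with pytest.raises(ValueError):
            allele_frequencies(gt, subset=[])

    def test_frequencies_sum_to_one(self, adult_freqs):
        for locus, fmap in adult_freqs.freqs.items():
            assert abs(sum(fmap.values()) - 1.0) < 1e-12


class TestHeterozygosity:
    def test_unbiased_formula_two_homozygotes(self):
        gt = adults([[(1, 1)], [(2, 2)]])
        ho, he = heterozygosities(gt)["L1"]
        assert ho == 0.0
        assert he == pytest.approx(4 / 3 * 0.5)

    def test_all_heterozygous_gives_ho_one(self):
        gt = adults([[(1, 2)]] * 10)
        ho, _ = heterozygosities(gt)["L1"]
        assert ho == 1.0

    def test_single_sample_flagged(self):
        gt = adults([[(1, 2)]])
        assert heterozygosities(gt)["L1"] is None

    def test_he_invariant_under_allele_relabelling(self):
        genos = [[(1, 2)], [(2, 3)], [(1, 1)], [(3, 3)], [(1, 3)]]
        relabel = {1: 7, 2: 5, 3: 9}
        swapped = [[tuple(sorted((relabel[a], relabel[b])))] for (a, b), in genos]
        _, he1 = heterozygosities(adults(genos))["L1"]
        _, he2 = heterozygosities(adults(swapped))["L1"]
        assert he1 == pytest.approx(he2)
        assert 0.0 <= he1 <= 1.0


class TestHweExactTest:
    def test_monomorphic_locus_p_one(self):
        gt = adults([[(1, 1)]] * 10)
        res = hwe_exact_test(gt, "L1")
        assert res.p_value == 1.0
        assert res.method == "monomorphic"

    def test_heterozygote_excess_detected_by_enumeration(self):
        gt = adults([[(1, 2)]] * 20)
        res = hwe_exact_test(gt, "L1")
        assert res.method == "enumeration"
        assert res.p_value < 1e-3

    def test_too_few_samples_rejected(self):
        gt = adults([[(1, 2)]] * 4)
        with pytest.raises(ValueError):
            hwe_exact_test(gt, "L1")

    def test_monte_carlo_reproducible_and_agrees_with_enumeration(self):
        rng = np.random.default_rng(9)
        genos = []
        for _ in range(30):
            a, b = sorted(rng.choice(3, size=2, p=[0.5, 0.3, 0.2]) + 1)
            genos.append([(int(a), int(b))])
        gt = adults(genos)
        exact = hwe_exact_test(gt, "L1").p_value
        mc1 = hwe_exact_test(gt, "L1", enum_cap=1, mc_reps=50_000, seed=11)
        mc2 = hwe_exact_test(gt, "L1", enum_cap=1, mc_reps=50_000, seed=11)
        assert mc1.method == "monte_carlo"
        assert mc1.p_value == mc2.p_value
        assert mc1.p_value == pytest.approx(exact, abs=0.01)

    def test_p_values_uniform_under_null(self):
        # data simulated under HWE: exact p-values should be ~Uniform(0,1)
        from scipy import stats

        rng = np.random.default_rng(1)
        ps = []
        for _ in range(300):
            genos = []
            for _ in range(30):
                a, b = sorted(rng.choice(3, size=2) + 1)
                genos.append([(int(a), int(b))])
            ps.append(hwe_exact_test(adults(genos), "L1").p_value)
        ks = stats.kstest(ps, "uniform")
        # exact conditional p-values are discrete and conservative, so allow
        # a generous critical value
        assert ks.statistic < 0.15


def brute_exclusion_parent_pair(p):
    """3-level enumeration over offspring x candidate pair genotypes."""
    k = len(p)
    genos = [(i, j) for i in range(k) for j in range(i, k)]

    def gp(g):
        a, b = g
        return p[a] ** 2 if a == b else 2 * p[a] * p[b]

    total = 0.0
    for off in genos:
        for g1 in genos:
            for g2 in genos:
                a, b = off
                compat = (a in g1 and b in g2) or (b in g1 and a in g2)
                if not compat:
                    total += gp(off) * gp(g1) * gp(g2)
    return total


def brute_exclusion_second_parent(p):
    """Enumerate true mother x true father x transmissions x candidate."""
    k = len(p)
    genos = [(i, j) for i in range(k) for j in range(i, k)]

    def gp(g):
        a, b = g
        return p[a] ** 2 if a == b else 2 * p[a] * p[b]

    total = 0.0
    for mom in genos:
        for m_allele in set(mom):
            w_m = 1.0 if mom[0] == mom[1] else 0.5
            for f in range(k):
                off = (min(m_allele, f), max(m_allele, f))
                for cand in genos:
                    a, b = off
                    ok = (a in mom and b in cand) or (b in mom and a in cand)
                    if not ok:
                        total += gp(mom) * w_m * p[f] * gp(cand)
    return total


class TestExclusionProbability:
    # frozen oracle value, recorded from brute_exclusion_parent_pair before
    # the implementation existed: biallelic p=q=0.5 -> 0.28125
    def test_biallelic_equifrequent_matches_recorded_oracle(self):
        fr = AlleleFrequencies(freqs={"L1": {1: 0.5, 2: 0.5}}, n_copies={}, mode="empirical")
        res = exclusion_probability(fr)
        assert res.per_locus["L1"] == pytest.approx(0.28125)
        assert res.per_locus["L1"] == pytest.approx(
            brute_exclusion_parent_pair([0.5, 0.5])
        )

    @pytest.mark.parametrize("probs", [[0.5, 0.3, 0.2], [0.7, 0.1, 0.1, 0.1]])
    def test_parent_pair_matches_brute_force(self, probs):
        fr = AlleleFrequencies(
            freqs={"L1": {i + 1: q for i, q in enumerate(probs)}},
            n_copies={},
            mode="empirical",
        )
        res = exclusion_probability(fr)
        assert res.per_locus["L1"] == pytest.approx(brute_exclusion_parent_pair(probs))

    @pytest.mark.parametrize("probs", [[0.5, 0.5], [0.5, 0.3, 0.2]])
    def test_second_parent_matches_brute_force(self, probs):
        fr = AlleleFrequencies(
            freqs={"L1": {i + 1: q for i, q in enumerate(probs)}},
            n_copies={},
            mode="empirical",
        )
        res = exclusion_probability(fr, form="second_parent")
        assert res.per_locus["L1"] == pytest.approx(
            brute_exclusion_second_parent(probs)
        )

    def test_monomorphic_locus_excludes_nothing(self):
        fr = AlleleFrequencies(
            freqs={"L1": {1: 1.0}, "L2": {1: 1.0}}, n_copies={}, mode="empirical"
        )
        res = exclusion_probability(fr)
        assert res.combined == 0.0

    def test_monotone_in_number_of_equifrequent_alleles(self):
        values = []
        for k in range(2, 11):
            fr = AlleleFrequencies(
                freqs={"L1": {i: 1.0 / k for i in range(k)}}, n_copies={}, mode="empirical"
            )
            values.append(exclusion_probability(fr).per_locus["L1"])
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_forms_are_ordered_second_parent_strongest(self):
        fr = AlleleFrequencies(
            freqs={"L1": {i: 0.25 for i in range(4)}}, n_copies={}, mode="empirical"
        )
        pp = exclusion_probability(fr, "parent_pair").per_locus["L1"]
        fp = exclusion_probability(fr, "first_parent").per_locus["L1"]
        sp = exclusion_probability(fr, "second_parent").per_locus["L1"]
        assert fp < sp < pp


class TestHaplotypeDiversity:
    def test_two_plus_two(self):
        hd = haplotype_diversity({"a": "H1", "b": "H1", "c": "H2", "d": "H2"})
        assert hd == pytest.approx(4 / 3 * 0.5)

    def test_single_haplotype_zero(self):
        assert haplotype_diversity({"a": "H1", "b": "H1"}) == 0.0

    def test_fewer_than_two_samples_error(self):
        with pytest.raises(ValueError):
            haplotype_diversity({"a": "H1"})

    def test_19_samples_13_haplotypes_always_bracket_field_estimate(self):
        # enumerate every composition of 19 into 13 positive counts
        def compositions(total, parts, minimum=1):
            if parts == 1:
                yield (total,)
                return
            for first in range(minimum, total - (parts - 1) + 1):
                for rest in compositions(total - first, parts - 1, first):
                    yield (first,) + rest

        hds = []
        for counts in compositions(19, 13):
            hap_of = {}
            i = 0
            for h, c in enumerate(counts):
                for _ in range(c):
                    hap_of[f"s{i}"] = f"H{h}"
                    i += 1
            hds.append(haplotype_diversity(hap_of))
        assert min(hds) >= 0.877
        assert max(hds) <= 0.965
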