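"""Diversity indexes and SFS neutrality statistics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from hapsurv.sfsstats import (
    DegenerateError,
    MissingOutgroupError,
    diversity,
    diversity_ztest,
    faywu_h,
    fuli_df,
    neutrality,
    neutrality_pvalues,
    tajima_d,
)

from conftest import simple_alignment


def brute_force_pi_total(seqs):
    """Mean pairwise difference count over all sequence pairs."""
    pairs = list(itertools.combinations(seqs, 2))
    return sum(sum(a != b for a, b in zip(x, y)) for x, y in pairs) / len(pairs)


def random_alignment(rng, n, L):
    seqs = {}
    base = rng.choice(list("ACGT"), size=L)
    for i in range(n):
        s = base.copy()
        nmut = rng.integers(0, L // 2)
        for site in rng.choice(L, size=nmut, replace=False):
            s[site] = rng.choice([b for b in "ACGT" if b != s[site]])
        seqs[f"s{i}"] = "".join(s)
    return simple_alignment(seqs, coding=())


class TestDiversity:
    def test_two_sequences_single_difference(self):
        aln = simple_alignment({"a": "A" * 10, "b": "A" * 9 + "T"}, coding=())
        d = diversity(aln)
        assert d.pi == pytest.approx(0.1)
        assert d.S == 1
        assert d.theta_w == pytest.approx(0.1)   # a1 = 1 for n = 2

    def test_four_distinct_haplotypes(self):
        aln = simple_alignment(
            {"a": "AAA", "b": "AAT", "c": "ATA", "d": "TAA"}, coding=()
        )
        d = diversity(aln)
        assert d.Hd == pytest.approx((4 / 3) * (1 - 4 * (1 / 16)))
        assert d.h == 4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pi_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=5, L=12)
        d = diversity(aln)
        expected = brute_force_pi_total(aln.ingroup_seqs) / aln.length
        assert d.pi == pytest.approx(expected, abs=1e-12)

    def test_biallelic_multiallelic_partition(self):
        aln = simple_alignment(
            {"a": "AAAA", "b": "ATAA", "c": "AGCA"}, coding=()
        )
        d = diversity(aln)
        # site 1 carries three states, site 2 two states
        assert d.S == 2 and d.sg == 1 and d.m3 == 1
        assert d.sg + d.m3 == d.S

    def test_sy_nsy_classification(self):
        # TTT/TTC synonymous polymorphism; GCA/CCA replacement polymorphism
        aln = simple_alignment(
            {"a": "TTTGCA", "b": "TTCGCA", "c": "TTTCCA"}
        )
        d = diversity(aln)
        assert d.Sy == 1 and d.NSy == 1

    def test_site_counts_sum_to_coding_length(self):
        aln = simple_alignment({"a": "TTTGCA", "b": "TTCGCA", "c": "TTTCCA"})
        d = diversity(aln)
        assert d.Ls + d.La == pytest.approx(6.0)

    def test_pathway_recombination_identity(self):
        """(Ls*pi_s + La*pi_a)/(Ls+La) recovers coding pi on codons with
        identical site counts and no multi-hit codons."""
        # GGx (Gly, fourfold) and GCx (Ala, fourfold): every haplotype has
        # the same synonymous-site total; one synonymous and one
        # replacement difference segregate
        aln = simple_alignment(
            {"a": "GGAGCA", "b": "GGTGCA", "c": "GGAGGA"}
        )
        d = diversity(aln)
        combined = (d.Ls * d.pi_s + d.La * d.pi_a) / (d.Ls + d.La)
        assert combined == pytest.approx(d.pi, abs=1e-9)


class TestTajimaD:
    def test_no_segregating_sites_is_nan(self):
        aln = simple_alignment({"a": "AAA", "b": "AAA"}, coding=())
        assert math.isnan(tajima_d(aln))

    def test_singleton_excess_negative(self):
        # every variant private to one sequence
        seqs = {f"s{i}": "".join("T" if j == i else "A" for j in range(10))
                for i in range(10)}
        assert tajima_d(simple_alignment(seqs, coding=())) < 0

    def test_matches_independent_formula(self):
        """Fixed 6x8 toy equals an independently coded evaluation to 1e-12."""
        seqs = {
            "s1": "AAAAAAAA",
            "s2": "AAAAAAAT",
            "s3": "AAAATAAT",
            "s4": "ACAATAAT",
            "s5": "ACAATAAA",
            "s6": "ACGATAAA",
        }
        aln = simple_alignment(seqs, coding=())
        n = 6
        pi = brute_force_pi_total(tuple(seqs.values()))
        S = sum(1 for i in range(8) if len({s[i] for s in seqs.values()}) > 1)
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajima_d(aln) == pytest.approx(expected, abs=1e-12)


class TestFuLi:
    def outgrouped(self, seqs):
        return simple_alignment(seqs, outgroup="og", coding=())

    def test_requires_outgroup(self):
        aln = simple_alignment({"a": "AAT", "b": "AAA"}, coding=())
        with pytest.raises(MissingOutgroupError):
            fuli_df(aln)

    def test_no_singletons_positive(self):
        # one intermediate-frequency variant, no derived singletons
        seqs = {"a": "TTAA", "b": "TTAA", "c": "AAAA", "d": "AAAA",
                "og": "AAAA"}
        D, F = fuli_df(self.outgrouped(seqs))
        assert D > 0 and F > 0

    def test_all_derived_singletons_negative(self):
        seqs = {f"s{i}": "".join("T" if j == i else "A" for j in range(6))
                for i in range(6)}
        seqs["og"] = "A" * 6
        D, F = fuli_df(self.outgrouped(seqs))
        assert D < 0 and F < 0

    def test_matches_independent_formula(self):
        seqs = {
            "s1": "TAAAAA",
            "s2": "TAAAAT",
            "s3": "TATAAT",
            "s4": "AATAAT",
            "og": "AAAAAA",
        }
        aln = self.outgrouped(seqs)
        D, F = fuli_df(aln)
        n = 4
        ingroup = [s for k, s in seqs.items() if k != "og"]
        # derived states polarized against the outgroup
        eta = eta_e = 0
        for col in range(6):
            states = {s[col] for s in ingroup}
            if len(states) < 2:
                continue
            for state in states - {"A"}:   # outgroup is all-A
                eta += 1
                eta_e += sum(s[col] == state for s in ingroup) == 1
        a = sum(1 / i for i in range(1, n))
        b = sum(1 / i**2 for i in range(1, n))
        c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
        vD = 1 + (a**2 / (b + a**2)) * (c - (n + 1) / (n - 1))
        uD = a - 1 - vD
        expected_D = (eta - a * eta_e) / math.sqrt(uD * eta + vD * eta**2)
        an1 = a + 1 / n
        vF = (c + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (a**2 + b)
        uF = (1 + (n + 1) / (3 * (n - 1))
              - 4 * ((n + 1) / (n - 1) ** 2) * (an1 - 2 * n / (n + 1))) / a - vF
        k = brute_force_pi_total(ingroup)
        expected_F = (k - eta_e) / math.sqrt(uF * eta + vF * eta**2)
        assert D == pytest.approx(expected_D, abs=1e-12)
        assert F == pytest.approx(expected_F, abs=1e-12)


class TestFayWu:
    def test_no_variation_zero(self):
        aln = simple_alignment({"a": "AAA", "b": "AAA", "og": "AAA"},
                               outgroup="og", coding=())
        theta_pi, theta_h, H, _ = faywu_h(aln)
        assert H == 0.0

    def test_high_frequency_derived_negative(self):
        # derived T at count n-1 of n
        seqs = {f"s{i}": "T" + "A" * 5 for i in range(5)}
        seqs["s5"] = "A" * 6
        seqs["og"] = "A" * 6
        aln = simple_alignment(seqs, outgroup="og", coding=())
        _, _, H, _ = faywu_h(aln)
        assert H < 0

    def test_matches_hand_enumeration(self):
        seqs = {
            "s1": "TAAA",
            "s2": "TAAT",
            "s3": "TAAT",
            "s4": "AAAT",
            "og": "AAAA",
        }
        aln = simple_alignment(seqs, outgroup="og", coding=())
        n = 4
        # derived counts: site 0 -> T carried by 3; site 3 -> T carried by 3
        expected_pi = 2 * (2 * 3 * 1 / (n * (n - 1)))
        expected_h = 2 * (2 * 9 / (n * (n - 1)))
        theta_pi, theta_h, H, skipped = faywu_h(aln)
        assert theta_pi == pytest.approx(expected_pi)
        assert theta_h == pytest.approx(expected_h)
        assert H == pytest.approx(expected_pi - expected_h)
        assert skipped == 0

    def test_unpolarizable_sites_skipped_and_reported(self):
        # outgroup carries a state absent from the ingroup at the variable site
        aln = simple_alignment({"a": "AAT", "b": "AAC", "og": "AAG"},
                               outgroup="og", coding=())
        *_, skipped = faywu_h(aln)
        assert skipped == 1


class TestZTest:
    def test_equal_estimates(self):
        z, p = diversity_ztest(0.01, 0.002, 0.01, 0.002)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_published_synonymous_nonsynonymous_contrast(self):
        # pi_a vs pi_s with their printed standard deviations
        z, p = diversity_ztest(0.006, 0.0010, 0.027, 0.0021)
        assert z == pytest.approx(-9.029, abs=5e-3)
        assert p < 1e-10

    def test_three_sigma(self):
        z, p = diversity_ztest(3 * math.hypot(0.3, 0.4), 0.3, 0.0, 0.4)
        assert p == pytest.approx(0.0027, abs=2e-4)

    def test_degenerate(self):
        with pytest.raises(DegenerateError):
            diversity_ztest(1.0, 0.0, 2.0, 0.0)


class TestSimulatedNull:
    def test_observed_zero_has_large_p(self):
        p = neutrality_pvalues({"tajima_D": 0.0}, n=20, S=10, reps=200, seed=1)
        assert p["tajima_D"] > 0.5

    def test_extreme_observation_hits_smoothing_floor(self):
        p = neutrality_pvalues({"tajima_D": 50.0}, n=20, S=10, reps=200, seed=1)
        assert p["tajima_D"] == pytest.approx(1 / 201)

    def test_neutrality_report_without_outgroup(self):
        aln = simple_alignment({"a": "AAT", "b": "AAA", "c": "ATA", "d": "AAA"},
                               coding=())
        r = neutrality(aln)
        assert r.fuli_D is None and r.faywu_H is None
        assert math.isfinite(r.tajima_D)
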