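import itertools
import math

import numpy as np
import pytest

from stallscan.core import Peak
from stallscan.enrichment import (NullModel, benjamini_hochberg, empirical_p,
                                  enumerate_null_scores, null_score_matrix,
                                  permutation_test, sample_placements,
                                  score_usrs, window_presence)
from stallscan.peaks import extract_usr
from conftest import make_gene


def peaks_with_usrs(gene, positions):
    return [extract_usr(Peak(gene.gene_id, c, 9.0), gene) for c in positions]


class TestScoring:
    def test_all_usrs_contain_target(self, poly_lysine_gene):
        peaks = peaks_with_usrs(poly_lysine_gene, [40, 50, 60])
        assert score_usrs(peaks, {"K"}) == 3

    def test_no_hit_scores_zero(self):
        gene = make_gene("g", 100)  # poly-alanine background
        peaks = peaks_with_usrs(gene, [40])
        assert score_usrs(peaks, {"K", "R", "H"}) == 0

    def test_mixed_charge_usr_counts_for_both_classes(self):
        gene = make_gene("g", 100, substitutions={35: "AAA", 36: "GAT"})  # K and D
        peaks = peaks_with_usrs(gene, [40])
        assert score_usrs(peaks, {"D", "E"}) == 1
        assert score_usrs(peaks, {"K", "R", "H"}) == 1

    def test_empty_peaks_score_zero(self):
        assert score_usrs([], {"K"}) == 0


class TestEmpiricalP:
    def test_counting_formula(self):
        null = np.array([49] * 963 + [50] * 17 + [60] * 20)
        assert empirical_p(50, null, "enriched") == pytest.approx(0.037)

    def test_extremes(self):
        null = np.arange(10, 30)
        assert empirical_p(5, null, "enriched") == 1.0
        assert empirical_p(5, null, "depleted") == 0.0

    def test_ecdf_identity(self, rng):
        null = rng.integers(0, 20, size=1000)
        for obs in range(0, 21):
            ecdf = np.mean(null <= obs - 1)
            assert empirical_p(obs, null, "enriched") == pytest.approx(1 - ecdf)

    def test_tie_inclusive_sides_sum_to_at_least_one(self, rng):
        null = rng.integers(0, 10, size=500)
        for obs in range(0, 11):
            p_sum = (empirical_p(obs, null, "enriched")
                     + empirical_p(obs, null, "depleted"))
            assert p_sum >= 1.0


class TestBenjaminiHochberg:
    def test_matches_textbook_step_up(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
                      0.212, 0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341,
                      0.384, 0.569, 0.594, 0.696])
        # textbook step-up oracle: q_(i) = min_{j>=i} m * p_(j) / j
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(benjamini_hochberg(p), expected)


class TestRandomization:
    def test_per_gene_peak_counts_preserved(self, rng):
        genes = {f"g{i}": make_gene(f"g{i}", 80) for i in range(3)}
        elig = {g: np.arange(31, 79) for g in genes}
        null = NullModel(n_randomizations=50, seed=4, eligible_positions=elig)
        counts = {"g0": 2, "g1": 5, "g2": 1}
        placements = sample_placements(null, counts)
        for g, k in counts.items():
            assert placements[g].shape == (50, k)
            # without replacement within each draw
            assert all(len(set(row)) == k for row in placements[g])

    def test_saturated_draw_forced_to_eligible_set(self):
        elig = {"g": np.array([31, 40, 55])}
        null = NullModel(n_randomizations=10, seed=0, eligible_positions=elig)
        placements = sample_placements(null, {"g": 3})
        for row in placements["g"]:
            assert sorted(row) == [31, 40, 55]

    def test_gene_with_too_many_peaks_skipped(self):
        elig = {"g": np.array([31, 40])}
        null = NullModel(n_randomizations=10, seed=0, eligible_positions=elig)
        assert sample_placements(null, {"g": 3}) == {}

    def test_same_seed_reproducible(self):
        elig = {"g": np.arange(31, 60)}
        counts = {"g": 3}
        a = sample_placements(NullModel(100, 7, elig), counts)
        b = sample_placements(NullModel(100, 7, elig), counts)
        np.testing.assert_array_equal(a["g"], b["g"])


class TestEnumerationAgreement:
    def _toy(self):
        # windows over eligible positions 31..42 differ: K visible only from
        # some positions, W from all, P from a couple
        g1 = make_gene("g1", 50, substitutions={36: "AAA", 20: "TGG", 40: "CCT"})
        g2 = make_gene("g2", 50, substitutions={40: "AAA"})
        genes = {"g1": g1, "g2": g2}
        elig = {"g1": np.arange(31, 43), "g2": np.arange(31, 43)}
        counts = {"g1": 2, "g2": 1}
        return genes, elig, counts

    def test_null_distribution_matches_exhaustive_enumeration(self):
        genes, elig, counts = self._toy()
        targets = {a: frozenset(a) for a in "KPW"}
        exact = enumerate_null_scores(genes, counts, elig, targets)
        assert exact.shape[0] == math.comb(12, 2) * 12

        # independent brute-force oracle over all placements
        pres = {g: window_presence(genes[g]) for g in genes}
        oracle = []
        for c1 in itertools.combinations(elig["g1"], 2):
            for c2 in itertools.combinations(elig["g2"], 1):
                row = []
                for aa in "KPW":
                    from stallscan.core import AA_INDEX
                    j = AA_INDEX[aa]
                    s = sum(pres["g1"][p, j] for p in c1)
                    s += sum(pres["g2"][p, j] for p in c2)
                    row.append(s)
                oracle.append(row)
        np.testing.assert_array_equal(np.sort(exact, axis=0),
                                      np.sort(np.array(oracle), axis=0))

    def test_monte_carlo_p_within_three_se_of_exact(self):
        genes, elig, counts = self._toy()
        targets = {a: frozenset(a) for a in "KPW"}
        exact = enumerate_null_scores(genes, counts, elig, targets)
        null = NullModel(n_randomizations=1000, seed=13, eligible_positions=elig)
        placements = sample_placements(null, counts)
        mc = null_score_matrix(placements, genes, [frozenset(a) for a in "KPW"])
        checked_intermediate = 0
        for t in range(3):
            for obs in range(int(exact[:, t].max()) + 2):
                p_exact = float(np.mean(exact[:, t] >= obs))
                p_mc = float(np.mean(mc[:, t] >= obs))
                se = math.sqrt(p_exact * (1 - p_exact) / 1000)
                assert abs(p_mc - p_exact) <= 3 * se + 1e-12
                if 0.05 < p_exact < 0.95:
                    checked_intermediate += 1
        assert checked_intermediate >= 2  # the toy is non-degenerate


class TestPermutationTest:
    def test_gene_order_invariance(self, rng):
        genes = {f"g{i}": make_gene(f"g{i}", 80,
                                    substitutions={35 + i: "AAA"}) for i in range(4)}
        elig = {g: np.arange(31, 79) for g in genes}
        peaks = [extract_usr(Peak(g, 45, 9.0), genes[g]) for g in genes]
        null = NullModel(200, 3, elig)
        t1, _, _ = permutation_test(genes, peaks, null, {"K": frozenset("K")})
        t2, _, _ = permutation_test(dict(reversed(list(genes.items()))),
                                    list(reversed(peaks)), null,
                                    {"K": frozenset("K")})
        assert t1.equals(t2)
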