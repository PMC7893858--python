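"""Rank-sum test, codon-identity matrices and the random-encoding baseline."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from codonscope import (
    ProteinSeq,
    Strategy,
    expected_uniform_identity,
    make_fixture_set,
    pairwise_codon_identity,
    random_protein,
    random_reverse_translation_baseline,
    rank_sum_test,
    reproducibility_report,
    significance_label,
    toy_table,
    validate_cds,
)
from codonscope.compare import CompareError


class TestRankSum:
    def test_identical_samples(self):
        r = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.z == 0.0 and r.p_two_sided == 1.0
        assert r.method == "normal_tie_corrected"  # ties force the approximation

    def test_complete_separation_exact(self):
        r = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0.0
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(0.1)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=12), rng.normal(1.0, size=9)
        assert rank_sum_test(a, b).p_two_sided == pytest.approx(
            rank_sum_test(b, a).p_two_sided
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(CompareError):
            rank_sum_test([], [1.0])

    def test_exact_matches_scipy_on_all_small_tie_free_samples(self):
        """Exhaustive check against scipy's exact U distribution for
        every tie-free sample shape with n1, n2 <= 6 (samples taken as
        rank subsets, which covers all tie-free configurations)."""
        for n1 in range(1, 7):
            for n2 in range(n1, 7):
                n = n1 + n2
                for subset in itertools.combinations(range(1, n + 1), n1):
                    a = list(subset)
                    b = [x for x in range(1, n + 1) if x not in subset]
                    r = rank_sum_test(a, b)
                    assert r.method == "exact"
                    ref = mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact").pvalue
                    assert r.p_two_sided == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = rng.integers(0, 6, size=15).astype(float)
            b = rng.integers(1, 7, size=20).astype(float)
            r = rank_sum_test(a, b)
            assert r.method == "normal_tie_corrected"
            ref = mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False).pvalue
            assert r.p_two_sided == pytest.approx(ref, rel=1e-9)

    def test_exact_and_normal_agree_on_tie_free_mid_sizes(self):
        """Exact p differs from the continuity-corrected normal tail by
        < 0.02 for tie-free samples of sizes 6-8."""
        rng = np.random.default_rng(10)
        for _ in range(20):
            n1, n2 = (int(x) for x in rng.integers(6, 9, size=2))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = pooled[:n1], pooled[n1:]
            exact = rank_sum_test(a, b)
            assert exact.method == "exact"
            mu = n1 * n2 / 2
            sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
            zc = (abs(exact.u_statistic - mu) - 0.5) / sigma
            approx = math.erfc(max(zc, 0.0) / math.sqrt(2))
            assert abs(exact.p_two_sided - approx) < 0.02


class TestSignificanceLabel:
    @pytest.mark.parametrize(
        "p,label",
        [(0.327, "n.s."), (0.011, "n.s."), (1.4e-3, "*"), (7.7e-4, "*"),
         (1e-6, "**"), (1.0, "n.s.")],
    )
    def test_thresholds(self, p, label):
        assert significance_label(p) == label

    def test_invalid_p_rejected(self):
        with pytest.raises(CompareError):
            significance_label(0.0)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        c = validate_cds("AAAAATGCA", "a")
        m = pairwise_codon_identity([c, validate_cds("AAAAATGCA", "b")])
        assert m.matrix[0, 1] == 100.0
        assert m.mean_offdiag == 100.0

    def test_one_difference_in_four_codons(self):
        a = validate_cds("AAAAATGCAGGT", "a")
        b = validate_cds("AAGAATGCAGGT", "b")
        m = pairwise_codon_identity([a, b])
        assert m.matrix[0, 1] == 75.0

    def test_half_identity(self):
        a = validate_cds("AAAAAT", "a")
        b = validate_cds("AAGAAT", "b")
        assert pairwise_codon_identity([a, b]).matrix[0, 1] == 50.0

    def test_symmetric_with_unit_diagonal(self):
        _, reps = make_fixture_set(12, 4, Strategy(name="uniform", seed=3), seed=3)
        m = pairwise_codon_identity(reps)
        assert np.allclose(m.matrix, m.matrix.T)
        assert np.all(np.diag(m.matrix) == 100.0)

    def test_mean_invariant_under_reordering(self):
        _, reps = make_fixture_set(12, 5, Strategy(name="uniform", seed=6), seed=6)
        m1 = pairwise_codon_identity(reps)
        m2 = pairwise_codon_identity(list(reversed(reps)))
        assert m1.mean_offdiag == pytest.approx(m2.mean_offdiag)

    def test_length_mismatch_names_pair(self):
        a, b = validate_cds("AAA", "a"), validate_cds("AAAAAG", "b")
        with pytest.raises(CompareError, match="'a'.*'b'"):
            pairwise_codon_identity([a, b])

    def test_protein_mismatch_rejected(self):
        a, b = validate_cds("AAA", "a"), validate_cds("GCA", "b")
        with pytest.raises(CompareError, match="protein mismatch"):
            pairwise_codon_identity([a, b])


class TestBaseline:
    def test_single_codon_family_protein_pins_band_at_100(self):
        band = random_reverse_translation_baseline(
            [ProteinSeq("m", "MMMM")], n=5, seed=1
        )
        assert band.low == band.high == 100.0

    def test_two_codon_family_approaches_half(self):
        prot = ProteinSeq("k", "KKKK")
        band = random_reverse_translation_baseline([prot], n=60, seed=2)
        expect = expected_uniform_identity(prot)
        assert expect == 50.0
        # 3 s.e. of the mean over all off-diagonal pairs
        se = 100 * math.sqrt(0.25 / len(prot)) / math.sqrt(math.comb(60, 2))
        assert abs(band.low - 50.0) < 3 * se + 1.0

    def test_converges_to_analytic_expectation(self):
        """Mean identity matches sum(1/family size)/n_sites within 3 s.e."""
        prot = random_protein(60, 17)
        n = 200
        band = random_reverse_translation_baseline([prot], n=n, seed=17)
        expect = expected_uniform_identity(prot)
        from codonscope import standard_code

        code = standard_code()
        ps = [1.0 / len(code.family(aa)) for aa in prot.sequence]
        var_pair = sum(p * (1 - p) for p in ps) / len(ps) ** 2
        se = 100 * math.sqrt(var_pair) / math.sqrt(math.comb(n, 2))
        assert abs(band.low - expect) < 3 * se

    def test_deterministic_given_seed(self):
        prot = random_protein(20, 9)
        b1 = random_reverse_translation_baseline([prot], n=10, seed=4)
        b2 = random_reverse_translation_baseline([prot], n=10, seed=4)
        assert b1 == b2

    def test_needs_two_replicates(self):
        with pytest.raises(CompareError):
            random_reverse_translation_baseline([ProteinSeq("m", "MK")], n=1)


class TestReproducibilityReport:
    def test_deterministic_strategy_scores_100_outside_band(self):
        table = toy_table()
        prot, reps = make_fixture_set(
            30, 3, Strategy(name="max_frequency", table=table), seed=5
        )
        report = reproducibility_report({"det": reps}, [prot], n_baseline=20, seed=5)
        assert report.means["det"] == 100.0
        assert not report.within_random_band["det"]

    def test_uniform_strategy_falls_inside_band(self):
        # band spans proteins of very different degeneracy (Lys: 2 codons,
        # ~50% expected identity; Leu: 6 codons, ~17%); a uniform replicate
        # set of a mixed protein (~39%) must land inside it
        prot, reps = make_fixture_set(60, 10, Strategy(name="uniform", seed=12), seed=12)
        proteins = [ProteinSeq("allK", "K" * 40), ProteinSeq("allL", "L" * 40), prot]
        report = reproducibility_report({"rand": reps}, proteins,
                                        n_baseline=50, seed=12)
        assert report.baseline.low < report.means["rand"] < report.baseline.high
        assert report.within_random_band["rand"]
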