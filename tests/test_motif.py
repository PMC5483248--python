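"""Unit and property tests for matrix construction and motif scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import rel_entr

from crescan import (
    BackgroundModel,
    CountMatrix,
    FrequencyMatrix,
    SiteCollection,
    ValidationError,
    build_count_matrix,
    build_pssm,
    consensus_sequence,
    degenerate_match,
    estimate_background,
    information_content,
    palindrome_positions,
    reverse_complement,
    sample_sites,
    score_kmer,
    to_frequencies,
)
from crescan.motif import ALPHABET, Pssm

from conftest import random_frequency_matrix, random_pssm

dna = st.text(alphabet="ACGT", min_size=2, max_size=20)
even_dna = dna.filter(lambda s: len(s) % 2 == 0)


class TestCountMatrix:
    def test_direct_tally(self):
        cm = build_count_matrix(SiteCollection(["ACG", "ACG"]))
        expected = np.zeros((4, 3), int)
        expected[0, 0] = expected[1, 1] = expected[2, 2] = 2
        np.testing.assert_array_equal(cm.counts, expected)

    def test_mixed_column(self):
        cm = build_count_matrix(SiteCollection(["AA", "TT"]))
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 0], [0, 0], [1, 1]])

    def test_columns_sum_to_n_sites_on_sampled_collections(self, cre_freqs):
        sites = sample_sites(cre_freqs, 44, seed=3)
        cm = build_count_matrix(sites)
        assert (cm.counts.sum(axis=0) == 44).all()

    @pytest.mark.parametrize(
        "bad_sites, fragment",
        [
            ([], "empty"),
            (["ACGT", "ACG"], "site 1"),
            (["ACGT", "ACNT"], "site 1"),
        ],
    )
    def test_invalid_collections_identify_offender(self, bad_sites, fragment):
        with pytest.raises(ValidationError, match=fragment):
            SiteCollection(bad_sites)


class TestFrequencies:
    def test_no_pseudocount_keeps_point_mass(self):
        cm = CountMatrix(counts=np.array([[2], [0], [0], [0]]), n_sites=2)
        fm = to_frequencies(cm, pseudocount=0)
        np.testing.assert_allclose(fm.f[:, 0], [1, 0, 0, 0])

    def test_laplace_smoothing(self):
        cm = CountMatrix(counts=np.array([[2], [0], [0], [0]]), n_sites=2)
        fm = to_frequencies(cm, pseudocount=1)
        np.testing.assert_allclose(fm.f[:, 0], [3 / 6, 1 / 6, 1 / 6, 1 / 6])

    def test_negative_pseudocount_rejected(self):
        cm = CountMatrix(counts=np.array([[1], [0], [0], [0]]), n_sites=1)
        with pytest.raises(ValidationError):
            to_frequencies(cm, pseudocount=-0.1)

    @given(
        columns=st.lists(
            st.lists(st.integers(0, 50), min_size=4, max_size=4),
            min_size=1,
            max_size=10,
        ),
        pseudocount=st.floats(0, 5, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_columns_are_stochastic(self, columns, pseudocount):
        """Every column of a frequency matrix sums to 1 regardless of input."""
        arr = np.array(columns).T  # (4, k)
        # pad row A so all columns share the same site count
        n = int(arr.sum(axis=0).max()) + 1
        arr[0] += n - arr.sum(axis=0)
        cm = CountMatrix(counts=arr, n_sites=n)
        fm = to_frequencies(cm, pseudocount)
        # independent re-summation
        sums = [sum(fm.f[b, i] for b in range(4)) for i in range(fm.width)]
        assert all(abs(s - 1) < 1e-9 for s in sums)


class TestBackground:
    def test_balanced_sequence_is_uniform(self):
        np.testing.assert_allclose(estimate_background("AACCGGTT").p, 0.25)

    def test_non_acgt_ignored(self):
        np.testing.assert_allclose(estimate_background("AANNCCGGTTxx").p, 0.25)

    def test_degenerate_genome_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            bg = estimate_background("AAAA")
        assert bg.p[0] > 0.99 and (bg.p > 0).all()
        with pytest.raises(ValidationError):
            estimate_background("AAAA", floor=0)

    def test_composition_recovered_from_sample(self, rng):
        p = np.array([0.3, 0.2, 0.2, 0.3])
        seq = "".join(rng.choice(list(ALPHABET), size=10_000, p=p))
        np.testing.assert_allclose(estimate_background(seq).p, p, atol=0.02)

    def test_both_strands_gives_strand_symmetric_background(self):
        bg = estimate_background("AAAAAACG", both_strands=True)
        assert bg.p[0] == bg.p[3] and bg.p[1] == bg.p[2]

    def test_empty_after_filtering_rejected(self):
        with pytest.raises(ValidationError):
            estimate_background("NNNN")


class TestPssm:
    def test_background_column_scores_zero(self):
        fm = FrequencyMatrix(f=np.full((4, 3), 0.25))
        pssm = build_pssm(fm)
        np.testing.assert_allclose(pssm.w, 0.0)
        assert score_kmer(pssm, "ACG") == 0.0

    def test_single_perfect_site_scores_2_bits_per_position(self):
        sites = SiteCollection(["ACGT"])
        fm = to_frequencies(build_count_matrix(sites), pseudocount=0)
        pssm = build_pssm(fm, zero_policy="allow")
        assert score_kmer(pssm, "ACGT") == pytest.approx(8.0)

    def test_strict_policy_rejects_zero_cells(self):
        fm = to_frequencies(build_count_matrix(SiteCollection(["ACGT"])), 0)
        with pytest.raises(ValidationError, match="zero"):
            build_pssm(fm, zero_policy="strict")

    def test_allow_policy_vetoes_unseen_bases(self):
        fm = to_frequencies(build_count_matrix(SiteCollection(["ACGT"])), 0)
        pssm = build_pssm(fm, zero_policy="allow")
        assert score_kmer(pssm, "TCGT") == -np.inf


class TestScoring:
    def test_additivity_against_per_position_loop(self, rng):
        pssm = random_pssm(rng, k=6)
        for _ in range(20):
            kmer = "".join(rng.choice(list(ALPHABET), size=6))
            expected = sum(
                pssm.w[ALPHABET.index(kmer[i]), i] for i in range(6)
            )
            assert score_kmer(pssm, kmer) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seq", ["ACG", "ACGTA", "ACNT"])
    def test_invalid_kmers_rejected(self, seq):
        pssm = Pssm(w=np.zeros((4, 4)))
        with pytest.raises(ValidationError):
            score_kmer(pssm, seq)

    def test_consensus_beats_exhaustive_enumeration(self, rng):
        for k in (3, 4, 5):
            pssm = random_pssm(rng, k=k)
            seq, score = consensus_sequence(pssm)
            best = max(
                score_kmer(pssm, "".join(kmer))
                for kmer in itertools.product(ALPHABET, repeat=k)
            )
            assert score == pytest.approx(best, abs=1e-12)

    def test_consensus_tie_breaks_lexicographically(self):
        w = np.zeros((4, 2))
        w[1, 0] = w[2, 0] = 1.0  # C and G tie at position 0
        w[0, 1] = 1.0
        seq, _ = consensus_sequence(Pssm(w=w))
        assert seq == "CA"

    def test_perfect_conservation_bound(self):
        """With pseudocount 0 and uniform background the ceiling is 2 bits
        per position, and any consensus score respects the column-max bound."""
        sites = SiteCollection(["TGAAAGCGCTTTCA"] * 5)
        fm = to_frequencies(build_count_matrix(sites), pseudocount=0)
        pssm = build_pssm(fm, zero_policy="allow")
        _, score = consensus_sequence(pssm)
        assert score == pytest.approx(2 * 14)
        assert score <= pssm.max_score + 1e-12


class TestInformationContent:
    def test_uniform_column_carries_no_information(self):
        fm = FrequencyMatrix(f=np.full((4, 2), 0.25))
        np.testing.assert_allclose(information_content(fm), 0.0)

    def test_point_mass_column_carries_two_bits(self):
        fm = FrequencyMatrix(f=np.array([[1.0], [0], [0], [0]]))
        np.testing.assert_allclose(information_content(fm), [2.0])

    def test_matches_scipy_relative_entropy(self, rng):
        fm = random_frequency_matrix(rng, k=8)
        bg = BackgroundModel(p=rng.dirichlet(np.ones(4)))
        expected = rel_entr(fm.f, bg.p[:, None]).sum(axis=0) / np.log(2)
        np.testing.assert_allclose(information_content(fm, bg), expected, atol=1e-12)

    def test_mean_background_score_is_minus_kl(self, rng):
        """E[score | background] = -sum_i KL(p || f_i), always <= 0."""
        fm = random_frequency_matrix(rng, k=5)
        bg = BackgroundModel.uniform()
        pssm = build_pssm(fm, bg)
        expected = -rel_entr(bg.p[:, None] * np.ones((4, 5)), fm.f).sum() / np.log(2)
        assert expected <= 1e-12
        exact = float((bg.p[:, None] * pssm.w).sum())
        assert exact == pytest.approx(expected, abs=1e-9)


class TestPalindrome:
    @pytest.mark.parametrize(
        "seq, count",
        [
            ("TGAAAGCGCTTTCA", 7),  # optimum cre-type sequence: full dyad
            ("TGAACGCGCGTACA", 6),  # celC operator
            ("TGTAAACGGTGTCA", 4),  # manB site
            ("GTAAATCGGTTGCA", 3),  # celT site
            ("AT", 1),
            ("AA", 0),
        ],
    )
    def test_known_operator_counts(self, seq, count):
        report = palindrome_positions(seq)
        assert report.count == count
        assert report.half_width == len(seq) // 2
        assert sum(report.matches) == count

    @given(even_dna)
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_reverse_complement(self, seq):
        assert (
            palindrome_positions(reverse_complement(seq)).count
            == palindrome_positions(seq).count
        )

    @pytest.mark.parametrize("seq", ["ACG", "ANAT"])
    def test_rejects_odd_or_ambiguous(self, seq):
        with pytest.raises(ValidationError):
            palindrome_positions(seq)


class TestDegenerateMatch:
    def test_celc_against_cre_consensus_by_hand(self):
        # TGAACGCGCGTACA vs TGNAANCGNWNNCW, position by position:
        # T=T G=G A inN A=A | C!=A | G inN C=C G=G C inN | G notinW | T inN
        # A inN C=C A inW  -> 2 mismatches
        full, mism = degenerate_match("TGAACGCGCGTACA", "TGNAANCGNWNNCW")
        assert (full, mism) == (False, 2)

    def test_all_n_matches_anything(self):
        assert degenerate_match("TGTAAACGGTGTCA", "N" * 14) == (True, 0)

    def test_b_excludes_adenine(self):
        assert degenerate_match("A", "B") == (False, 1)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValidationError, match="IUPAC"):
            degenerate_match("A", "Z")

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_sequence_matches_itself(self, seq):
        assert degenerate_match(seq, seq) == (True, 0)
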