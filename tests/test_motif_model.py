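"""Matrix construction, scoring, consensus, comparison and discovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peg3motif import (
    build_count_matrix,
    compare_motifs,
    consensus,
    discover_motif,
    information_content,
    reverse_complement,
    reverse_complement_matrix,
    score,
)
from peg3motif.motif_model import BASES, MotifMatrix, _column_pearson

sites_strategy = st.lists(
    st.text(alphabet="ACGT", min_size=8, max_size=8), min_size=1, max_size=20
)
eightmer = st.text(alphabet="ACGT", min_size=8, max_size=8)


class TestBuildCountMatrix:
    def test_single_site_tally(self):
        m = build_count_matrix(["GTGGCAGT"])
        for i, b in enumerate("GTGGCAGT"):
            col = m.counts[:, i]
            assert col[BASES.index(b)] == 1 and col.sum() == 1

    def test_manual_four_site_tally(self):
        m = build_count_matrix(["GTGGCAGT", "TTGGCAGT", "GTGGCCGT", "GTGGCAGT"])
        assert m.counts[BASES.index("G"), 0] == 3
        assert m.counts[BASES.index("T"), 0] == 1
        assert m.counts[BASES.index("A"), 5] == 3
        assert m.counts[BASES.index("C"), 5] == 1
        assert m.nsites == 4

    def test_sites_sampled_from_matrix_reproduce_consensus(self, high_matrix):
        from peg3motif.synthetic_data import sample_site

        rng = np.random.default_rng(3)
        sites = [sample_site(high_matrix, rng, temperature=0.5) for _ in range(12)]
        rebuilt = build_count_matrix(sites)
        assert consensus(rebuilt, 0.5) == consensus(high_matrix, 0.5)

    def test_empty_and_ragged_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_count_matrix([])
        with pytest.raises(ValueError, match="ragged"):
            build_count_matrix(["ACGTACGT", "ACGT"])


class TestConsensus:
    def test_identity_on_unanimous_sites(self):
        m = build_count_matrix(["GTGGCAGT"] * 12)
        assert consensus(m) == "GTGGCAGT"

    def test_even_gc_split_renders_s(self):
        m = MotifMatrix(np.array([[0.0], [6.0], [6.0], [0.0]]), alpha=0)
        assert consensus(m) == "S"

    def test_uniform_column_renders_n(self):
        m = MotifMatrix(np.full((4, 1), 3.0), alpha=0)
        assert consensus(m) == "N"

    def test_threshold_validated(self, high_matrix):
        with pytest.raises(ValueError):
            consensus(high_matrix, 0.0)
        with pytest.raises(ValueError):
            consensus(high_matrix, 1.5)

    @given(s=eightmer, k=st.integers(1, 10))
    def test_consensus_of_repeated_site_is_the_site(self, s, k):
        assert consensus(build_count_matrix([s] * k)) == s


class TestScore:
    def test_one_site_closed_form(self):
        # f(match) = (1 + 0.25)/2 = 0.625; 8 * log2(0.625/0.25)
        m = build_count_matrix(["GTGGCAGT"], alpha=1.0)
        assert score(m, "GTGGCAGT") == pytest.approx(8 * np.log2(2.5))
        assert score(m, "GTGGCAGT") == pytest.approx(10.575, abs=1e-3)

    def test_uniform_matrix_scores_zero(self):
        m = MotifMatrix(np.full((4, 8), 3.0), alpha=0)
        assert score(m, "GTGGCAGT") == pytest.approx(0.0)

    def test_best_window_attains_max_score(self, high_matrix):
        best = "".join(
            BASES[int(i)] for i in np.argmax(high_matrix.logodds, axis=0)
        )
        assert score(high_matrix, best) == pytest.approx(high_matrix.max_score)

    def test_n_contributes_zero(self, high_matrix):
        assert score(high_matrix, "NTGGCAGT") == pytest.approx(
            score(high_matrix, "GTGGCAGT") - high_matrix.logodds[BASES.index("G"), 0]
        )

    def test_length_mismatch_rejected(self, high_matrix):
        with pytest.raises(ValueError, match="length"):
            score(high_matrix, "ACGT")

    @given(sites=sites_strategy, window=eightmer)
    def test_strand_consistency_identity(self, sites, window):
        """Minus-strand scoring == forward scoring of the revcomp window."""
        m = build_count_matrix(sites)
        assert score(reverse_complement_matrix(m), window) == pytest.approx(
            score(m, reverse_complement(window))
        )


class TestInformationContent:
    def test_pure_column_two_bits(self):
        m = MotifMatrix(np.array([[4.0], [0], [0], [0]]), alpha=0)
        assert information_content(m)[0] == pytest.approx(2.0)

    def test_uniform_column_zero_bits(self):
        m = MotifMatrix(np.full((4, 1), 1.0), alpha=0)
        assert information_content(m)[0] == pytest.approx(0.0)

    def test_half_half_column_one_bit(self):
        m = MotifMatrix(np.array([[2.0], [2.0], [0], [0]]), alpha=0)
        assert information_content(m)[0] == pytest.approx(1.0)

    @given(sites=sites_strategy)
    def test_bounded_between_zero_and_two(self, sites):
        ic = information_content(build_count_matrix(sites))
        assert (ic >= -1e-9).all() and (ic <= 2 + 1e-9).all()


class TestReverseComplementMatrix:
    def test_one_site_matrix_maps_to_revcomp_site(self):
        m = build_count_matrix(["GTGGCAGT"])
        rc = reverse_complement_matrix(m)
        expected = build_count_matrix(["ACTGCCAC"])
        assert np.array_equal(rc.counts, expected.counts)

    @given(sites=sites_strategy)
    def test_involution_and_column_sums(self, sites):
        m = build_count_matrix(sites)
        rc2 = reverse_complement_matrix(reverse_complement_matrix(m))
        assert np.array_equal(rc2.counts, m.counts)
        rc = reverse_complement_matrix(m)
        assert np.array_equal(rc.counts.sum(axis=0), m.counts.sum(axis=0))


class TestCompareMotifs:
    def test_self_comparison(self, high_matrix):
        cmp_ = compare_motifs(high_matrix, high_matrix)
        assert (cmp_.offset, cmp_.orientation) == (0, "forward")
        assert cmp_.correlation == pytest.approx(1.0)

    def test_against_own_reverse_complement(self, high_matrix):
        cmp_ = compare_motifs(high_matrix, reverse_complement_matrix(high_matrix))
        assert cmp_.orientation == "reverse"
        assert cmp_.correlation == pytest.approx(1.0)

    def test_surrogates_align_on_shared_core(self, high_matrix, low_matrix):
        """The high and low motifs superpose their TGGC cores (offset +1)."""
        cmp_ = compare_motifs(high_matrix, low_matrix)
        assert (cmp_.offset, cmp_.orientation) == (1, "forward")

    def test_correlation_symmetry(self, high_matrix, low_matrix):
        f1, f2 = high_matrix.freqs, low_matrix.freqs
        d = 2
        fwd = np.mean(
            [_column_pearson(f1[:, i], f2[:, i - d]) for i in range(d, 8)]
        )
        rev = np.mean(
            [_column_pearson(f2[:, j], f1[:, j + d]) for j in range(0, 8 - d)]
        )
        assert fwd == pytest.approx(rev)

    def test_min_overlap_validated(self, high_matrix):
        with pytest.raises(ValueError):
            compare_motifs(high_matrix, high_matrix, min_overlap=9)


class TestDiscoverMotif:
    def test_recovers_planted_motif(self):
        rng = np.random.default_rng(7)
        seqs = []
        for _ in range(20):
            s = "".join(BASES[i] for i in rng.integers(4, size=60))
            pos = int(rng.integers(0, 52))
            seqs.append(s[:pos] + "GTGGCAGT" + s[pos + 8:])
        m = discover_motif(seqs, width=8, seed=1)
        assert consensus(m) == "GTGGCAGT"

    def test_identical_embedded_eightmer(self):
        seqs = ["A" * 10 + "GTGGCAGT" + "A" * 10] * 5
        m = discover_motif(seqs, width=8, max_iter=2, seed=0)
        assert consensus(m) == "GTGGCAGT"

    def test_random_input_less_informative_than_planted(self):
        rng = np.random.default_rng(11)
        rand = ["".join(BASES[i] for i in rng.integers(4, size=40))
                for _ in range(8)]
        planted = [s[:16] + "GTGGCAGT" + s[24:] for s in rand]
        ic_rand = information_content(discover_motif(rand, seed=0)).mean()
        ic_planted = information_content(discover_motif(planted, seed=0)).mean()
        assert ic_planted > ic_rand

    def test_width_longer_than_shortest_sequence_rejected(self):
        with pytest.raises(ValueError, match="width"):
            discover_motif(["ACGT", "ACGTACGTACGT"], width=8)


@given(sites=sites_strategy)
def test_frequencies_always_normalized(sites):
    """Every constructed matrix has columns of frequencies summing to 1."""
    for alpha in (0.0, 1.0, 4.0):
        m = build_count_matrix(sites, alpha=alpha)
        assert np.allclose(m.freqs.sum(axis=0), 1.0)
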