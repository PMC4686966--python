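"""Both-strand matrix scanning: planted-truth recovery and oracle parity."""

import numpy as np
import pytest

from peg3motif import (
    SequenceRecord,
    read_bed,
    reverse_complement,
    scan_fasta,
    scan_sequence,
    select_nonoverlapping,
    write_fasta,
)
from peg3motif.io_formats import GenomicInterval
from peg3motif.motif_model import score
from peg3motif.scanner import MotifHit


def brute_force_scan(seq, matrix, threshold_frac):
    """Independent oracle: per-offset python scoring of both strands."""
    w = matrix.width
    threshold = threshold_frac * matrix.max_score
    out = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if "N" in window:
            continue
        for strand, motif_seq in (("+", window), ("-", reverse_complement(window))):
            s = score(matrix, motif_seq)
            if s >= threshold:
                out.append((i, strand, round(s, 9)))
    return sorted(out)


class TestScanSequence:
    def test_planted_consensus_single_hit(self, high_matrix):
        seq = "A" * 10 + "GTGGCAGT" + "A" * 32
        hits = scan_sequence(SequenceRecord("r", seq), high_matrix, 0.8)
        assert len(hits) == 1
        (h,) = hits
        assert (h.start, h.end, h.strand, h.affinity_class) == (10, 18, "+", "high")

    def test_planted_revcomp_found_on_minus_strand(self, high_matrix):
        seq = "A" * 10 + "ACTGCCAC" + "A" * 32
        hits = scan_sequence(SequenceRecord("r", seq), high_matrix, 0.8)
        assert len(hits) == 1
        (h,) = hits
        assert (h.start, h.end, h.strand) == (10, 18, "-")
        assert h.motif_sequence == "GTGGCAGT"

    def test_background_yields_no_hits(self, high_matrix):
        hits = scan_sequence(SequenceRecord("r", "A" * 50), high_matrix, 0.8)
        assert hits == []

    def test_short_sequence_warns_and_returns_empty(self, high_matrix, caplog):
        with caplog.at_level("WARNING"):
            assert scan_sequence(SequenceRecord("r", "ACGT"), high_matrix) == []
        assert "shorter" in caplog.text

    def test_n_windows_skipped(self, high_matrix):
        seq = "A" * 10 + "GTGGCNGT" + "A" * 32
        assert scan_sequence(SequenceRecord("r", seq), high_matrix, 0.5) == []

    def test_matches_bruteforce_on_random_sequences(self, high_matrix):
        rng = np.random.default_rng(17)
        for _ in range(10):
            seq = "".join("ACGT"[i] for i in rng.integers(4, size=2000))
            rec = SequenceRecord("r", seq)
            got = sorted(
                (h.start, h.strand, round(h.score, 9))
                for h in scan_sequence(rec, high_matrix, 0.5)
            )
            assert got == brute_force_scan(seq, high_matrix, 0.5)

    def test_threshold_monotonicity(self, high_matrix):
        rng = np.random.default_rng(23)
        seq = "".join("ACGT"[i] for i in rng.integers(4, size=5000))
        rec = SequenceRecord("r", seq)
        counts = [
            len(scan_sequence(rec, high_matrix, f)) for f in (0.2, 0.4, 0.6, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_strand_mirror(self, high_matrix):
        rng = np.random.default_rng(29)
        seq = "".join("ACGT"[i] for i in rng.integers(4, size=3000))
        L = len(seq)
        fwd = scan_sequence(SequenceRecord("r", seq), high_matrix, 0.6)
        rev = scan_sequence(
            SequenceRecord("r", reverse_complement(seq)), high_matrix, 0.6
        )
        reflected = sorted(
            (L - h.end, L - h.start, "+" if h.strand == "-" else "-") for h in rev
        )
        assert sorted((h.start, h.end, h.strand) for h in fwd) == reflected

    def test_threshold_frac_above_one_rejected(self, high_matrix):
        with pytest.raises(ValueError):
            scan_sequence(SequenceRecord("r", "A" * 20), high_matrix, 1.2)


class TestScanFasta:
    def test_planted_sites_recovered_with_bed_output(self, tmp_path, high_matrix):
        from peg3motif.synthetic_data import generate_genome, plant_sites

        records, _ = generate_genome(100_000, seed=31)
        records, truth = plant_sites(records, high_matrix, n_single=10, seed=32)
        fa = tmp_path / "g.fa"
        write_fasta(records, fa)
        bed = tmp_path / "hits.bed"
        n = scan_fasta(fa, high_matrix, 0.8, bed)
        assert n >= 10
        got = {(iv.start, iv.end, iv.strand) for iv in read_bed(bed)}
        planted = {
            (p.interval.start, p.interval.end, p.strand) for p in truth.planted_sites
        }
        assert planted <= got

    def test_empty_fasta_zero_hits_empty_bed(self, tmp_path, high_matrix):
        fa = tmp_path / "e.fa"
        fa.write_text("")
        bed = tmp_path / "hits.bed"
        assert scan_fasta(fa, high_matrix, 0.8, bed) == 0
        assert bed.read_text() == ""

    def test_deterministic_bed_output(self, tmp_path, high_matrix):
        from peg3motif.synthetic_data import generate_genome

        records, _ = generate_genome(50_000, seed=37)
        fa = tmp_path / "g.fa"
        write_fasta(records, fa)
        b1, b2 = tmp_path / "h1.bed", tmp_path / "h2.bed"
        scan_fasta(fa, high_matrix, 0.5, b1)
        scan_fasta(fa, high_matrix, 0.5, b2)
        assert b1.read_bytes() == b2.read_bytes()


def _hit(start, score, strand="+", chrom="r"):
    return MotifHit(
        GenomicInterval(chrom, start, start + 8, strand=strand),
        strand, float(score), "GTGGCAGT", "high",
    )


def brute_force_select(hits):
    """Max-score-first oracle with same-strand overlap exclusion."""
    remaining = sorted(hits, key=lambda h: (-h.score, h.start, h.strand))
    kept = []
    for h in remaining:
        if not any(
            k.strand == h.strand
            and k.interval.chrom == h.interval.chrom
            and h.start < k.end
            and k.start < h.end
            for k in kept
        ):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.interval.chrom, h.start, h.strand))


class TestSelectNonoverlapping:
    def test_overlapping_pair_keeps_higher_score(self):
        hits = [_hit(0, 10.0), _hit(4, 8.0)]
        assert select_nonoverlapping(hits) == [hits[0]]

    def test_disjoint_hits_all_kept(self):
        hits = [_hit(0, 5.0), _hit(20, 6.0), _hit(40, 7.0)]
        assert select_nonoverlapping(hits) == hits

    def test_opposite_strands_may_overlap(self):
        hits = [_hit(0, 10.0, "+"), _hit(4, 8.0, "-")]
        assert select_nonoverlapping(hits) == hits

    def test_matches_bruteforce_on_random_hit_sets(self):
        rng = np.random.default_rng(41)
        for _ in range(1000):
            n = int(rng.integers(0, 15))
            hits = [
                _hit(
                    int(rng.integers(0, 60)),
                    float(rng.integers(1, 50)),
                    "+-"[int(rng.integers(2))],
                )
                for _ in range(n)
            ]
            assert select_nonoverlapping(hits) == brute_force_select(hits)
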