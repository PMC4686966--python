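"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates inside the package are 0-based, half-open, on the
plus strand.  FASTA parsing/writing is delegated to :mod:`Bio.SeqIO`
(60-column wrap on output); BED, gene-model TSV and the two motif-matrix
dialects (JASPAR raw counts, MEME-minimal frequencies) have small dedicated
codecs with explicit precision and error contracts.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .motif_model import BASES, MotifMatrix

logger = logging.getLogger(__name__)

#: Non-ACGTN IUPAC nucleotide letters that are demoted to N on input.
_DEGENERATE_IUPAC = set("URYSWKMBDHV")
_ALPHABET = set("ACGTN")


@dataclass
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """BED-style interval: 0-based start, half-open end."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self}")
        if self.end <= self.start:
            raise ValueError(f"end <= start in {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """Minimal gene structure: TSS/TES plus an exon chain.

    ``exons`` are genomic (plus-strand) intervals ordered 5'->3' along the
    gene, i.e. ascending coordinates for a + gene and descending for a -
    gene.  ``tss``/``tes`` follow the same convention (tss > tes on -).
    """

    gene: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene}: - strand requires tss > tes")
        ordered = self.exons if self.strand == "+" else self.exons[::-1]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(
                    f"gene {self.gene}: exons must be sorted 5'->3' and disjoint"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic [start, end) of the transcription unit."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    def introns(self) -> list[tuple[int, int]]:
        """Introns in transcription (5'->3') order, as genomic intervals."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out


def normalize_sequence(raw: str, *, record_id: str = "?") -> tuple[str, int]:
    """Uppercase, demote degenerate IUPAC letters to N; return (seq, n_demoted)."""
    seq = raw.upper()
    demoted = sum(1 for c in seq if c in _DEGENERATE_IUPAC)
    if demoted:
        seq = "".join("N" if c in _DEGENERATE_IUPAC else c for c in seq)
        logger.warning(
            "record %s: %d degenerate IUPAC base(s) demoted to N", record_id, demoted
        )
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(
            f"record {record_id!r}: illegal characters {sorted(bad)} (not IUPAC DNA)"
        )
    return seq, demoted


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Raises on an empty file, duplicate ids, or characters outside the IUPAC
    DNA alphabet.  Degenerate IUPAC letters are mapped to N with a logged
    count.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq, _ = normalize_sequence(str(rec.seq), record_id=rec.id)
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; missing name/score/strand default to '.', 0, '.'."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: BED line has {len(fields)} column(s), need >= 3"
                )
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, name, score, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (score formatted as int when integral)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Packaged transcription of the published mm9 target table (21 rows)
# ---------------------------------------------------------------------------

TABLE1_RESOURCE = "table1_mm9.tsv"


def table1_fixture_path() -> Path:
    """Filesystem path of the packaged mm9 target-table transcription."""
    return Path(resources.files("peg3motif.data") / TABLE1_RESOURCE)


def read_table1_fixture(
    path: str | Path | None = None,
) -> list[tuple[GenomicInterval, str, str]]:
    """Parse the packaged 21-row mm9 target table.

    Printed coordinates are 1-based inclusive (MACS2 xls convention) and are
    converted to 0-based half-open as (start-1, end).  The category string is
    preserved verbatim.  Raises if the fixture does not hold exactly 21 rows.
    """
    path = table1_fixture_path() if path is None else Path(path)
    rows: list[tuple[GenomicInterval, str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["chr", "start", "end", "gene", "position"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start_s, end_s, gene, category = line.split("\t")
            iv = GenomicInterval(chrom, int(start_s) - 1, int(end_s), name=gene)
            rows.append((iv, gene, category))
    if len(rows) != 21:
        raise ValueError(
            f"{path}: target-table fixture corrupted: {len(rows)} rows, expected 21"
        )
    return rows


# ---------------------------------------------------------------------------
# Gene-model TSV
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene", "chrom", "strand", "tss", "tes", "exon_starts", "exon_ends"]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the TSV gene-model dialect (comma-separated exon lists)."""
    models: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLUMNS:
            raise ValueError(f"{path}: expected columns {_GENE_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            gene, chrom, strand, tss, tes, starts_s, ends_s = line.split("\t")
            starts = [int(x) for x in starts_s.split(",") if x]
            ends = [int(x) for x in ends_s.split(",") if x]
            if len(starts) != len(ends):
                raise ValueError(f"{path}:{lineno}: ragged exon lists")
            models.append(
                GeneModel(gene, chrom, strand, int(tss), int(tes),
                          list(zip(starts, ends)))
            )
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in models:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(
                f"{g.gene}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# Motif-matrix dialects
# ---------------------------------------------------------------------------

DIALECTS = ("jaspar", "meme-minimal")


def _format_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_matrix(
    path: str | Path,
    dialect: str,
    *,
    alpha: float = 1.0,
    background: Sequence[float] | None = None,
    name: str | None = None,
) -> MotifMatrix:
    """Read a motif matrix.

    jaspar
        Raw counts, preserved exactly (full float precision on write).
    meme-minimal
        Column frequencies; counts are reconstructed as frequency x nsites
        with the pseudocount set to zero so the frequencies round-trip.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown matrix dialect {dialect!r}; choose from {DIALECTS}")
    text = Path(path).read_text()
    if dialect == "jaspar":
        from Bio import motifs as _bio_motifs

        parsed = _bio_motifs.parse(io.StringIO(text), "jaspar")
        if not parsed:
            raise ValueError(f"{path}: no JASPAR records")
        motif = parsed[0]
        counts = np.array([list(motif.counts[b]) for b in BASES], dtype=float)
        if (counts < 0).any():
            raise ValueError(f"{path}: negative counts")
        return MotifMatrix(
            counts, alpha=alpha, background=background, name=name or motif.name
        )
    return _read_meme_minimal(text, str(path), name=name)


def _read_meme_minimal(text: str, origin: str, name: str | None) -> MotifMatrix:
    lines = [ln.rstrip() for ln in text.splitlines()]
    background = np.full(4, 0.25)
    it = iter(enumerate(lines))
    motif_name = None
    for _, ln in it:
        if ln.startswith("Background letter frequencies"):
            _, bg_line = next(it)
            toks = bg_line.split()
            background = np.array(
                [float(dict(zip(toks[::2], toks[1::2]))[b]) for b in BASES]
            )
        elif ln.startswith("MOTIF"):
            motif_name = ln.split(maxsplit=1)[1].strip() or None
        elif ln.startswith("letter-probability matrix"):
            attrs = dict(
                (k.rstrip("="), v)
                for k, v in zip(ln.split()[2::2], ln.split()[3::2])
            )
            width = int(attrs["w"])
            nsites = float(attrs.get("nsites", 20))
            freqs = []
            for _ in range(width):
                _, row = next(it)
                vals = [float(x) for x in row.split()]
                if len(vals) != 4:
                    raise ValueError(f"{origin}: matrix row has {len(vals)} fields")
                freqs.append(vals)
            f = np.array(freqs).T  # (4, width)
            if (f < 0).any():
                raise ValueError(f"{origin}: negative frequencies")
            return MotifMatrix(
                f * nsites,
                alpha=0.0,
                background=background,
                name=name or motif_name,
            )
    raise ValueError(f"{origin}: no MEME letter-probability matrix found")


def write_matrix(matrix: MotifMatrix, path: str | Path, dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown matrix dialect {dialect!r}; choose from {DIALECTS}")
    name = matrix.name or "motif"
    with open(path, "w") as fh:
        if dialect == "jaspar":
            fh.write(f">{name}\n")
            for b, row in zip(BASES, matrix.counts):
                cells = " ".join(_format_count(c) for c in row)
                fh.write(f"{b} [ {cells} ]\n")
        else:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\n")
            fh.write(
                " ".join(f"{b} {p:g}" for b, p in zip(BASES, matrix.background))
                + "\n\n"
            )
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {matrix.width} "
                f"nsites= {matrix.nsites:g} E= 0\n"
            )
            freqs = matrix.freqs
            for i in range(matrix.width):
                # round to 6 dp, then absorb the rounding residue into the
                # largest entry so every written column sums to exactly 1
                col = np.round(freqs[:, i], 6)
                col[int(np.argmax(col))] += round(1.0 - col.sum(), 6)
                fh.write(" " + " ".join(f"{x:.6f}" for x in col) + "\n")
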