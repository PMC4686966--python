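"""Seeded generators for every input the pipeline consumes.

No raw data accompany the source study, so all recovery tests run against
synthetic inputs with known ground truth: i.i.d. background genomes at a
mouse-like GC content with motif occurrences planted singly or as
opposite-orientation pairs with short spacers, competitor 8-mer panels
built around the TGGC core, random multi-exon gene models, and qPCR Ct
tables with planted fold changes and Gaussian cycle noise.  Every generator
is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    read_bed,
    write_bed,
)
from .motif_model import BASES, MotifMatrix, reverse_complement

PlantKind = Literal["single", "composite_member"]


@dataclass(frozen=True)
class PlantedSite:
    interval: GenomicInterval
    strand: str
    kind: PlantKind
    source: str  # matrix name
    pair_id: int | None = None  # shared by the two members of a composite


@dataclass
class SyntheticTruth:
    planted_sites: list[PlantedSite] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def singles(self) -> list[PlantedSite]:
        return [p for p in self.planted_sites if p.kind == "single"]

    def composite_pairs(self) -> dict[int, list[PlantedSite]]:
        pairs: dict[int, list[PlantedSite]] = {}
        for p in self.planted_sites:
            if p.kind == "composite_member":
                pairs.setdefault(p.pair_id, []).append(p)
        return pairs


def truth_to_bed(truth: SyntheticTruth, path: str | Path) -> None:
    """Write planted sites as BED6; the name field encodes kind/source/pair."""
    ivs = [
        GenomicInterval(
            p.interval.chrom, p.interval.start, p.interval.end,
            name=f"{p.kind}|{p.source}|{'' if p.pair_id is None else p.pair_id}",
            score=0.0, strand=p.strand,
        )
        for p in truth.planted_sites
    ]
    write_bed(ivs, path)


def truth_from_bed(path: str | Path) -> SyntheticTruth:
    sites = []
    for iv in read_bed(path):
        kind, source, pair = iv.name.split("|")
        sites.append(
            PlantedSite(
                GenomicInterval(iv.chrom, iv.start, iv.end),
                iv.strand, kind, source,  # type: ignore[arg-type]
                None if pair == "" else int(pair),
            )
        )
    return SyntheticTruth(planted_sites=sites)


def generate_genome(
    length: int,
    gc_fraction: float = 0.42,
    n_contigs: int = 1,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """I.i.d. background genome at the requested base composition."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    probs = [at, gc, gc, at]  # A C G T
    base_arr = np.frombuffer("ACGT".encode(), dtype="S1")
    per = length // n_contigs
    records = []
    for i in range(n_contigs):
        n = per if i < n_contigs - 1 else length - per * (n_contigs - 1)
        draws = rng.choice(4, size=n, p=probs)
        records.append(
            SequenceRecord(f"contig{i + 1}", base_arr[draws].tobytes().decode())
        )
    truth = SyntheticTruth(
        parameters={
            "operation": "generate_genome", "length": length,
            "gc_fraction": gc_fraction, "n_contigs": n_contigs, "seed": seed,
        }
    )
    return records, truth


def sample_site(matrix: MotifMatrix, rng: np.random.Generator,
                temperature: float = 0.0) -> str:
    """Draw one site from a matrix; temperature 0 yields the consensus base
    (column argmax), temperature 1 the matrix frequencies themselves."""
    f = matrix.freqs
    out = []
    for i in range(matrix.width):
        col = f[:, i]
        if temperature <= 0:
            out.append(BASES[int(np.argmax(col))])
        else:
            p = col ** (1.0 / temperature)
            p = p / p.sum()
            out.append(BASES[int(rng.choice(4, p=p))])
    return "".join(out)


def plant_sites(
    records: Sequence[SequenceRecord],
    matrix: MotifMatrix,
    n_single: int = 0,
    n_composite: int = 0,
    spacer_dist: int | tuple[int, int] = (0, 10),
    opposite_fraction: float = 1.0,
    min_separation: int = 200,
    temperature: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Overwrite genome positions with motif sites; coordinates stay stable.

    Singles are placed on a random strand.  Composites are two sampled
    sites separated by a spacer drawn from ``spacer_dist`` (an int or an
    inclusive (lo, hi) range); the second member is reverse-complemented
    (minus strand) with probability ``opposite_fraction``.  Footprints keep
    at least ``min_separation`` bp between each other; placement failing
    1000 attempts raises.
    """
    rng = np.random.default_rng(seed)
    w = matrix.width
    source = matrix.name or "matrix"
    seqs = {r.id: list(r.seq) for r in records}
    lengths = {r.id: len(r.seq) for r in records}
    ids = [r.id for r in records]
    occupied: dict[str, list[tuple[int, int]]] = {rid: [] for rid in ids}
    truth = SyntheticTruth(
        parameters={
            "operation": "plant_sites", "n_single": n_single,
            "n_composite": n_composite, "spacer_dist": spacer_dist,
            "opposite_fraction": opposite_fraction,
            "min_separation": min_separation, "temperature": temperature,
            "seed": seed, "source": source,
        }
    )

    def place(size: int) -> tuple[str, int]:
        for _ in range(1000):
            rid = ids[int(rng.integers(len(ids)))]
            L = lengths[rid]
            if L < size:
                continue
            start = int(rng.integers(0, L - size + 1))
            lo, hi = start - min_separation, start + size + min_separation
            if all(e <= lo or s >= hi for s, e in occupied[rid]):
                occupied[rid].append((start, start + size))
                return rid, start
        raise ValueError(
            "could not place a site without overlap after 1000 attempts"
        )

    def draw_spacer() -> int:
        if isinstance(spacer_dist, int):
            return spacer_dist
        lo, hi = spacer_dist
        return int(rng.integers(lo, hi + 1))

    def write_site(rid: str, start: int, site: str, strand: str) -> None:
        planted = site if strand == "+" else reverse_complement(site)
        seqs[rid][start : start + w] = planted

    for _ in range(n_single):
        rid, start = place(w)
        strand = "+" if rng.random() < 0.5 else "-"
        site = sample_site(matrix, rng, temperature)
        write_site(rid, start, site, strand)
        truth.planted_sites.append(
            PlantedSite(GenomicInterval(rid, start, start + w), strand,
                        "single", source)
        )

    for pair_id in range(n_composite):
        spacer = draw_spacer()
        size = 2 * w + spacer
        rid, start = place(size)
        site1 = sample_site(matrix, rng, temperature)
        site2 = sample_site(matrix, rng, temperature)
        strand2 = "-" if rng.random() < opposite_fraction else "+"
        start2 = start + w + spacer
        write_site(rid, start, site1, "+")
        write_site(rid, start2, site2, strand2)
        for st, strand in ((start, "+"), (start2, strand2)):
            truth.planted_sites.append(
                PlantedSite(GenomicInterval(rid, st, st + w), strand,
                            "composite_member", source, pair_id)
            )

    new_records = [SequenceRecord(r.id, "".join(seqs[r.id])) for r in records]
    return new_records, truth


def generate_competitors(
    n_high: int = 12,
    n_low: int = 12,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Labeled competitor 8-mers around the TGGC core.

    High members carry the high register (G1, TGGC at 2-5, T8); low members
    alternate between the shifted-core form (TGGC at 1-4) and the
    register-kept form missing the G1 or T8 preference.  ``mutation_rate``
    then mutates each base independently, degrading label accuracy.
    """
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []

    def rbase() -> str:
        return BASES[int(rng.integers(4))]

    def gc() -> str:
        return "GC"[int(rng.integers(2))]

    for _ in range(n_high):
        out.append(("G" + "TGGC" + rbase() + gc() + "T", "high"))
    for i in range(n_low):
        if i % 2 == 0:
            seq = "TGGC" + rbase() + gc() + rbase() + "C"  # shifted core
        else:
            first = "ACT"[int(rng.integers(3))]  # core kept, G1 lost
            seq = first + "TGGC" + rbase() + gc() + "T"
        out.append((seq, "low"))

    if mutation_rate > 0:
        mutated = []
        for seq, label in out:
            chars = list(seq)
            for j, c in enumerate(chars):
                if rng.random() < mutation_rate:
                    chars[j] = BASES[(BASES.index(c) + 1 + int(rng.integers(3))) % 4]
            mutated.append(("".join(chars), label))
        out = mutated
    return out


def generate_gene_models(
    n_genes: int,
    genome_length: int,
    seed: int = 0,
    chrom: str = "contig1",
    margin: int = 12_000,
) -> list[GeneModel]:
    """Random non-overlapping 3-exon genes on both strands.

    Genes are laid out in evenly spaced slots with jitter so neighboring
    promoter/flank windows stay clear of each other; raises when the genome
    cannot hold the requested genes with the margin.
    """
    rng = np.random.default_rng(seed)
    usable = genome_length - 2 * margin
    slot = usable // max(n_genes, 1)
    max_span = 3 * 300 + 2 * 1500
    if n_genes < 1 or slot < max_span + margin:
        raise ValueError(
            f"genome of {genome_length} bp cannot hold {n_genes} genes "
            f"with {margin} bp margins"
        )
    models: list[GeneModel] = []
    for i in range(n_genes):
        exon_sizes = rng.integers(150, 301, size=3)
        intron_sizes = rng.integers(500, 1501, size=2)
        span = int(exon_sizes.sum() + intron_sizes.sum())
        slot_start = margin + i * slot
        start = slot_start + int(rng.integers(0, slot - span - margin + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        bounds = []
        pos = start
        for k in range(3):
            bounds.append((pos, pos + int(exon_sizes[k])))
            pos += int(exon_sizes[k])
            if k < 2:
                pos += int(intron_sizes[k])
        end = pos
        if strand == "+":
            exons, tss, tes = bounds, start, end
        else:
            exons, tss, tes = bounds[::-1], end, start
        models.append(GeneModel(f"gene{i + 1:03d}", chrom, strand, tss, tes, exons))
    return models


def generate_ct_table(
    fold_changes: Mapping[str, Mapping[str, float]],
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    reference_gene: str = "Actb",
    calibrator_group: str = "WT",
    test_group: str = "KO",
) -> pd.DataFrame:
    """Ct table with planted fold changes (test group relative to calibrator).

    The reference gene cycles around a constant baseline in every group;
    each target's test-group Ct is shifted by -log2(fold) so that the Livak
    estimator recovers the planted panel exactly at zero noise.  Gaussian
    noise of ``noise_sd`` cycles is added per well.
    """
    for gene, tissues in fold_changes.items():
        for tissue, fold in tissues.items():
            if fold <= 0:
                raise ValueError(f"fold for {gene}/{tissue} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    tissues = sorted({t for m in fold_changes.values() for t in m})
    ref_base = 17.0
    for tissue in tissues:
        target_base = {
            gene: float(rng.uniform(22, 26)) for gene in sorted(fold_changes)
        }
        for group in (calibrator_group, test_group):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (group, tissue, reference_gene, rep,
                     ref_base + rng.normal(0, noise_sd) if noise_sd else ref_base)
                )
            for gene in sorted(fold_changes):
                if tissue not in fold_changes[gene]:
                    continue
                shift = (
                    -np.log2(fold_changes[gene][tissue])
                    if group == test_group else 0.0
                )
                for rep in range(1, n_replicates + 1):
                    ct = target_base[gene] + shift
                    if noise_sd:
                        ct += rng.normal(0, noise_sd)
                    rows.append((group, tissue, gene, rep, ct))
    return pd.DataFrame(
        rows, columns=["group", "tissue", "gene", "replicate", "ct"]
    )
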