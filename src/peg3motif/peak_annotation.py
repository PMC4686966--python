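"""Assign promoter/enhancer/intergenic categories to peak intervals.

Reproduces the published target-table vocabulary: promoter, 5' enhancer,
3' enhancer, enhancer (1st intron), enhancer (intron), intergenic.  The
source study states no window sizes, so the operational definitions are
package defaults (all configurable): the promoter is TSS-1000..TSS+500 in
gene orientation, the 5'/3' enhancer windows are the 10-kb flanks upstream
of the promoter window and downstream of the TES, and intronic categories
require overlap with an intron (first intron distinguished).  Precedence
when a peak qualifies for several categories of one gene:
promoter > intron > 5' flank > 3' flank.  Across genes, the
highest-precedence category wins; ties go to the smaller |TSS distance|,
then the lexicographically smaller gene name.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .io_formats import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

CATEGORIES = (
    "promoter",
    "enhancer_intron1",
    "enhancer_intron",
    "enhancer_5prime",
    "enhancer_3prime",
    "intergenic",
)

#: precedence rank; intronic categories share one tier
_RANK = {
    "promoter": 0,
    "enhancer_intron1": 1,
    "enhancer_intron": 1,
    "enhancer_5prime": 2,
    "enhancer_3prime": 3,
}

#: verbatim category strings of the published table -> internal enum
TABLE_CATEGORY_MAP = {
    "promoter": "promoter",
    "5' enhancer": "enhancer_5prime",
    "3' enhancer": "enhancer_3prime",
    "enhancer (1st intron)": "enhancer_intron1",
    "enhancer (intron)": "enhancer_intron",
}


def normalize_category(label: str) -> str:
    """Map a printed category string (case-insensitive) to the enum."""
    key = label.strip().lower()
    for printed, cat in TABLE_CATEGORY_MAP.items():
        if printed.lower() == key:
            return cat
    raise ValueError(f"unknown category label {label!r}")


@dataclass(frozen=True)
class PeakAnnotation:
    peak: GenomicInterval
    gene: Optional[str]
    category: str
    distance_to_tss: Optional[int]

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (self.gene is None):
            raise ValueError("gene must be None exactly when category is intergenic")


def _overlap(peak: GenomicInterval, start: int, end: int) -> bool:
    return start < end and peak.start < end and start < peak.end


def _categorize_for_gene(
    peak: GenomicInterval,
    g: GeneModel,
    promoter_up: int,
    promoter_down: int,
    flank: int,
) -> Optional[str]:
    """Best (highest-precedence) category of the peak w.r.t. one gene."""
    if peak.chrom != g.chrom:
        return None
    if g.strand == "+":
        prom = (g.tss - promoter_up, g.tss + promoter_down)
        enh5 = (prom[0] - flank, prom[0])
        enh3 = (g.tes, g.tes + flank)
    else:
        prom = (g.tss - promoter_down, g.tss + promoter_up)
        enh5 = (prom[1], prom[1] + flank)
        enh3 = (g.tes - flank, g.tes)
    if _overlap(peak, max(0, prom[0]), prom[1]):
        return "promoter"
    introns = g.introns()
    for idx, (s, e) in enumerate(introns):
        if _overlap(peak, s, e):
            return "enhancer_intron1" if idx == 0 else "enhancer_intron"
    if _overlap(peak, max(0, enh5[0]), enh5[1]):
        return "enhancer_5prime"
    if _overlap(peak, max(0, enh3[0]), enh3[1]):
        return "enhancer_3prime"
    return None


def _tss_distance(peak: GenomicInterval, g: GeneModel) -> int:
    """Signed gene-oriented distance from TSS to peak midpoint (+ = downstream)."""
    mid = (peak.start + peak.end) // 2
    return mid - g.tss if g.strand == "+" else g.tss - mid


def annotate_peak(
    peak: GenomicInterval,
    gene_models: Sequence[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 500,
    flank: int = 10_000,
) -> PeakAnnotation:
    """Annotate one peak against a set of gene models (see module docstring)."""
    if not gene_models:
        logger.warning("no gene models supplied; peak annotated intergenic")
        return PeakAnnotation(peak, None, "intergenic", None)
    candidates = []
    for g in gene_models:
        cat = _categorize_for_gene(peak, g, promoter_up, promoter_down, flank)
        if cat is not None:
            d = _tss_distance(peak, g)
            candidates.append((_RANK[cat], abs(d), g.gene, cat, d))
    if not candidates:
        return PeakAnnotation(peak, None, "intergenic", None)
    _, _, gene, cat, d = min(candidates)
    return PeakAnnotation(peak, gene, cat, d)


def annotate_peaks(
    peaks: Iterable[GenomicInterval],
    gene_models: Sequence[GeneModel],
    **windows: int,
) -> list[PeakAnnotation]:
    models = sorted(gene_models, key=lambda g: (g.chrom, g.span, g.gene))
    return [annotate_peak(p, models, **windows) for p in peaks]


@dataclass
class TargetSummary:
    n_peaks: int
    n_unique_genes: int
    category_counts: dict[str, int]
    n_gene_associated: int
    n_intergenic: int
    peaks_per_gene: dict[str, int]


AnnotationLike = Union[PeakAnnotation, tuple]


def summarize_targets(annotations: Iterable[AnnotationLike]) -> TargetSummary:
    """Tally peaks, unique genes, and category counts.

    Accepts :class:`PeakAnnotation` objects or the (interval, gene,
    category-string) tuples produced by the packaged target-table fixture
    (verbatim category strings are normalized case-insensitively).
    """
    cat_counts: Counter[str] = Counter()
    gene_counts: Counter[str] = Counter()
    n = 0
    for ann in annotations:
        n += 1
        if isinstance(ann, PeakAnnotation):
            gene, cat = ann.gene, ann.category
        else:
            _, gene, cat = ann
            cat = normalize_category(cat)
        cat_counts[cat] += 1
        if gene is not None:
            gene_counts[gene] += 1
    n_gene = sum(v for k, v in cat_counts.items() if k != "intergenic")
    return TargetSummary(
        n_peaks=n,
        n_unique_genes=len(gene_counts),
        category_counts={c: cat_counts.get(c, 0) for c in CATEGORIES},
        n_gene_associated=n_gene,
        n_intergenic=cat_counts.get("intergenic", 0),
        peaks_per_gene=dict(gene_counts),
    )
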