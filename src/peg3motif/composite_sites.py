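"""Paired (composite) motif occurrences within short spacers.

The strongest known PEG3 probe (from the Pgm2l1 promoter) carries two
motif-like sites 4 bp apart on opposite strands, and other target regions
show the same clustering, suggesting paired sites as a high-affinity
signature.  This module pairs scanned hits whose gap (end of the left hit
to start of the right hit, half-open coordinates) is between 0 and
``max_spacer``; "4 bp apart" maps to spacer = 4 under this convention.
Overlapping occurrences (negative gap) are not paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io_formats import SequenceRecord
from .motif_model import MotifMatrix
from .scanner import MotifHit, scan_sequence


@dataclass(frozen=True)
class CompositeSite:
    """Two motif hits on one record separated by a short spacer."""

    hit1: MotifHit  # leftmost
    hit2: MotifHit
    spacer: int
    orientation: Literal["same", "opposite"]

    @property
    def sub_orientation(self) -> str:
        """Metadata only: convergent (+/-), divergent (-/+), or tandem."""
        if self.orientation == "same":
            return "tandem"
        return "convergent" if self.hit1.strand == "+" else "divergent"

    @property
    def span(self) -> tuple[int, int]:
        return (self.hit1.start, self.hit2.end)


def find_composite_sites(
    hits: Sequence[MotifHit], max_spacer: int = 20
) -> list[CompositeSite]:
    """All hit pairs with 0 <= gap <= max_spacer, leftmost hit first.

    ``hits`` must come from a single record and be sorted by start; a hit
    may participate in several pairs.  Orientation is "same" iff the
    strands are equal (finer head-to-head/tail-to-tail geometry is exposed
    as :attr:`CompositeSite.sub_orientation` metadata).
    """
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    starts = [h.start for h in hits]
    if starts != sorted(starts):
        raise ValueError("hits must be sorted by start coordinate")
    chroms = {h.interval.chrom for h in hits}
    if len(chroms) > 1:
        raise ValueError(f"hits span multiple records: {sorted(chroms)}")
    out: list[CompositeSite] = []
    for i, h1 in enumerate(hits):
        for h2 in hits[i + 1 :]:
            spacer = h2.start - h1.end
            if spacer < 0:
                continue
            if spacer > max_spacer:
                break
            out.append(
                CompositeSite(
                    h1, h2, spacer,
                    "same" if h1.strand == h2.strand else "opposite",
                )
            )
    return out


def find_composites_in_record(
    record: SequenceRecord,
    matrix: MotifMatrix,
    partner_threshold_frac: float = 0.6,
    max_spacer: int = 20,
    max_rule_violations: int | None = None,
) -> list[CompositeSite]:
    """Scan a record at a (possibly permissive) threshold, then pair hits.

    The partner threshold may sit below the usual scan threshold — weak
    second sites are part of the composite signature — and may be <= 0 for
    partners that score below zero bits.  At very permissive thresholds,
    frame-shifted shadows of a strong site can outscore a genuine weak
    partner; setting ``max_rule_violations`` additionally requires every
    hit to violate at most that many critical/G-or-C position rules
    (:func:`peg3motif.affinity_rules.count_rule_violations`), which keeps
    only windows in a motif-compatible register.
    """
    hits = scan_sequence(record, matrix, threshold_frac=partner_threshold_frac)
    if max_rule_violations is not None:
        from .affinity_rules import count_rule_violations

        hits = [
            h for h in hits
            if count_rule_violations(h.motif_sequence) <= max_rule_violations
        ]
    return find_composite_sites(hits, max_spacer=max_spacer)


@dataclass
class DensityProfile:
    window: int
    counts: np.ndarray  # counts[j] = composites starting in [j, j + window)
    mean: float
    max: int
    argmax: list[int]


def composite_density(
    composites: Sequence[CompositeSite], length: int, window: int = 200
) -> DensityProfile:
    """Sliding-window composite counts over a record of the given length.

    A composite is counted in windows containing its leftmost start.  The
    window must be at least as wide as one motif occurrence.
    """
    if composites and window < len(composites[0].hit1.interval):
        raise ValueError("window narrower than the motif width")
    if window < 1 or length < window:
        raise ValueError("need 1 <= window <= length")
    n_windows = length - window + 1
    marks = np.zeros(length, dtype=int)
    for c in composites:
        marks[c.hit1.start] += 1
    cum = np.concatenate([[0], np.cumsum(marks)])
    counts = cum[window : window + n_windows] - cum[:n_windows]
    mx = int(counts.max()) if n_windows else 0
    return DensityProfile(
        window=window,
        counts=counts,
        mean=float(counts.mean()) if n_windows else 0.0,
        max=mx,
        argmax=[int(i) for i in np.flatnonzero(counts == mx)] if mx > 0 else [],
    )
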