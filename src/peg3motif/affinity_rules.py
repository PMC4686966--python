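"""Critical-position binding rules for the PEG3 8-mer site.

Competition assays split TGGC-containing probe regions into high- and
low-affinity classes.  The difference is captured by the register of the
TGGC core and two flanking preferences: high-affinity sites carry the core
at positions 2-5 with G at position 1 and T at position 8 (GTGGCAGT); sites
that keep the core but lose the G1 or T8 preference, or carry the core one
register left (positions 1-4, the TGGCACNC form), bind weakly; sites
without the core in either register do not bind.

The classifier is a heuristic tier: a few genuine high-affinity regions
violate individual preferences, so genome-scale predictions are gated by
matrix score thresholds in :mod:`peg3motif.scanner`, not by this rule set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

from .motif_model import BASES, MotifMatrix, reverse_complement, score

Affinity = Literal["high", "low", "none"]

CORE = "TGGC"


@dataclass(frozen=True)
class PositionRule:
    tier: Literal["critical", "preferred", "either_GC", "free"]
    allowed: frozenset[str]


@dataclass(frozen=True)
class RuleSet:
    """Per-position constraint tiers for the 8-bp site (1-based positions)."""

    width: int = 8
    core: str = CORE
    core_start: int = 2  # 1-based position of the core T in the high register
    constraints: dict[int, PositionRule] = field(
        default_factory=lambda: {
            1: PositionRule("preferred", frozenset("G")),
            2: PositionRule("critical", frozenset("T")),
            3: PositionRule("critical", frozenset("G")),
            4: PositionRule("critical", frozenset("G")),
            5: PositionRule("either_GC", frozenset("GC")),
            6: PositionRule("free", frozenset(BASES)),
            7: PositionRule("either_GC", frozenset("GC")),
            8: PositionRule("critical", frozenset("T")),
        }
    )


DEFAULT_RULESET = RuleSet()


def classify_affinity(window: str, ruleset: RuleSet = DEFAULT_RULESET) -> Affinity:
    """Classify an 8-mer as a high / low / non-binding site.

    Anchored on the TGGC core: core at positions 2-5 with G1 and T8 is
    high; core at 2-5 missing either preference is low; core only at
    positions 1-4 (the low-motif register) is low; no core in either
    register is none.
    """
    window = window.upper()
    if len(window) != ruleset.width:
        raise ValueError(f"window must be {ruleset.width} bp, got {len(window)}")
    if set(window) - set(BASES):
        raise ValueError(f"window {window!r} contains non-ACGT characters")
    core = ruleset.core
    k = ruleset.core_start - 1
    if window[k : k + 4] == core:
        if window[0] == "G" and window[7] == "T":
            return "high"
        return "low"
    if window[:4] == core:
        return "low"
    return "none"


def predict_mutation_effect(
    window: str,
    position: int | Sequence[int],
    new_base: str | Sequence[str],
    matrix: MotifMatrix,
) -> float:
    """Score change (bits) caused by point mutation(s) of a window.

    ``position`` is 1-based.  Multi-base mutations are applied sequentially;
    because the matrix score is additive the result equals the sum of the
    individual effects.  Mutating a base to itself contributes 0 and warns.
    """
    positions = [position] if isinstance(position, int) else list(position)
    bases = [new_base] if isinstance(new_base, str) else list(new_base)
    if len(positions) != len(bases):
        raise ValueError("position and new_base lists differ in length")
    mutant = list(window.upper())
    for pos, b in zip(positions, bases):
        if not 1 <= pos <= len(mutant):
            raise ValueError(f"position {pos} outside 1..{len(mutant)}")
        b = b.upper()
        if b not in BASES:
            raise ValueError(f"bad base {b!r}")
        if mutant[pos - 1] == b:
            warnings.warn(
                f"identity mutation at position {pos} ({b}->{b})", stacklevel=2
            )
        mutant[pos - 1] = b
    return score(matrix, "".join(mutant)) - score(matrix, window)


def count_rule_violations(
    window: str,
    ruleset: RuleSet = DEFAULT_RULESET,
    tiers: Sequence[str] = ("critical", "either_GC"),
) -> int:
    """Number of positions whose base falls outside the allowed set.

    Only rules of the listed tiers are counted (by default the invariant
    core/critical positions and the G-or-C positions; the softer
    "preferred" tier is ignored).  Useful for telling a genuinely
    motif-like window from a frame-shifted shadow of a neighboring site,
    which matrix score alone cannot always do.
    """
    window = window.upper()
    if len(window) != ruleset.width:
        raise ValueError(f"window must be {ruleset.width} bp, got {len(window)}")
    n = 0
    for pos, rule in ruleset.constraints.items():
        if rule.tier in tiers and window[pos - 1] not in rule.allowed:
            n += 1
    return n


class CoreCandidate(NamedTuple):
    offset: int  # plus-strand start of the 8-mer interval
    window: str  # motif-strand 8-mer (core in the high register)
    strand: str


def extract_core_candidates(seq: str, ruleset: RuleSet = DEFAULT_RULESET) -> list[CoreCandidate]:
    """All 8-mer windows holding a TGGC core in the high register.

    For each TGGC at offset k on either strand, the window [k-1, k+7) on the
    motif strand is emitted when fully in bounds.  Minus-strand windows are
    reported as plus-strand intervals (offset of the interval start) with a
    strand flag; the ``window`` field reads along the motif strand.
    """
    seq = seq.upper()
    L = len(seq)
    out: list[CoreCandidate] = []
    if L < ruleset.width:
        return out
    core = ruleset.core
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        k = s.find(core)
        while k != -1:
            if k >= 1 and k + 7 <= L:
                window = s[k - 1 : k + 7]
                if strand == "+":
                    offset = k - 1
                else:
                    offset = L - (k + 7)
                out.append(CoreCandidate(offset, window, strand))
            k = s.find(core, k + 1)
    out.sort(key=lambda c: (c.offset, c.strand))
    return out
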