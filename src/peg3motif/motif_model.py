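"""Position-specific matrix model of the PEG3 binding site.

The zinc-finger repressor PEG3 recognizes an 8-bp site whose high-affinity
form is 5'-GTGGCAGT-3'.  This module holds the matrix machinery around that
motif: count matrices built from aligned competitor sites, pseudocounted
frequencies and log-odds scores, IUPAC consensus calling, per-position
information content, ungapped motif-vs-motif comparison, and a miniature
greedy motif-discovery routine.

Scores are log2 odds against a background base composition, so the score of
a window is in bits and the expected score of background sequence is
negative.  The published matrix cells are not machine-readable, so the
package ships *surrogate* canonical matrices (:func:`surrogate_high_matrix`,
:func:`surrogate_low_matrix`) that encode the documented constraint tiers:
positions 3, 4 and 8 invariant (G/G/T), core T at position 2, preferred G at
position 1, G-or-C at positions 5 and 7, position 6 unconstrained beyond a
preference for A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC code for each non-empty subset of {A, C, G, T}.
IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A=0, C=1, G=2, T=3, N=4."""
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"illegal base {exc.args[0]!r}") from None


@dataclass
class AlignedSiteSet:
    """An ungapped alignment of fixed-width binding sites (no N allowed)."""

    sites: list[str]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("empty site set")
        w = len(self.sites[0])
        for s in self.sites:
            if len(s) != w:
                raise ValueError(f"ragged site widths: {len(s)} vs {w}")
            if set(s) - set(BASES):
                raise ValueError(f"site {s!r} contains non-ACGT characters")
        if w < 4:
            raise ValueError(f"site width {w} < 4")

    @property
    def width(self) -> int:
        return len(self.sites[0])


class MotifMatrix:
    """Per-position base counts with pseudocounted frequencies and log-odds.

    Parameters
    ----------
    counts
        (4, width) array of non-negative reals, rows in A, C, G, T order.
        Column sums must be equal across positions (the site count N).
    alpha
        Total pseudocount, distributed by background:
        f(b, i) = (c(b, i) + alpha * p(b)) / (N + alpha).
    background
        Background base probabilities p(b) (default uniform).
    """

    def __init__(
        self,
        counts: np.ndarray | Sequence[Sequence[float]],
        *,
        alpha: float = 1.0,
        background: Sequence[float] | None = None,
        name: str | None = None,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"counts must be (4, width), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("negative counts")
        if alpha < 0:
            raise ValueError("pseudocount alpha must be >= 0")
        colsums = counts.sum(axis=0)
        if not np.allclose(colsums, colsums[0]):
            raise ValueError(f"column sums differ: {colsums}")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if bg.shape != (4,) or (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 positive probabilities summing to 1")
        self.counts = counts
        self.alpha = float(alpha)
        self.background = bg
        self.name = name

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def nsites(self) -> float:
        return float(self.counts[:, 0].sum())

    @property
    def freqs(self) -> np.ndarray:
        """(4, width) pseudocounted frequencies; columns sum to 1."""
        return (self.counts + self.alpha * self.background[:, None]) / (
            self.nsites + self.alpha
        )

    @property
    def logodds(self) -> np.ndarray:
        """(4, width) log2(f/p) scores; zero-frequency cells are -inf."""
        f = self.freqs
        with np.errstate(divide="ignore"):
            return np.log2(f / self.background[:, None])

    @property
    def max_score(self) -> float:
        """Score of the best possible window (sum of column maxima)."""
        return float(self.logodds.max(axis=0).sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MotifMatrix(name={self.name!r}, width={self.width}, "
            f"nsites={self.nsites:g}, alpha={self.alpha:g})"
        )


def build_count_matrix(
    sites: AlignedSiteSet | Sequence[str],
    *,
    alpha: float = 1.0,
    background: Sequence[float] | None = None,
    name: str | None = None,
) -> MotifMatrix:
    """Tally aligned sites into a count matrix (N = number of sites)."""
    if not isinstance(sites, AlignedSiteSet):
        sites = AlignedSiteSet(list(sites))
    w = sites.width
    counts = np.zeros((4, w))
    for s in sites.sites:
        codes = encode(s)
        counts[codes, np.arange(w)] += 1
    return MotifMatrix(counts, alpha=alpha, background=background, name=name)


def consensus(matrix: MotifMatrix, degeneracy_threshold: float = 0.25) -> str:
    """IUPAC consensus: per column, the code for {b : f(b,i) >= threshold}.

    With the default threshold of 0.25 a fully unconstrained column (all
    frequencies 0.25) renders as N, matching the published low-affinity
    motif notation TGGCACnC.
    """
    if not 0 < degeneracy_threshold <= 1:
        raise ValueError("degeneracy_threshold must be in (0, 1]")
    f = matrix.freqs
    out = []
    for i in range(matrix.width):
        bases = frozenset(
            b for b, j in _BASE_INDEX.items() if j < 4 and f[j, i] >= degeneracy_threshold
        )
        if not bases:  # threshold > 0.25 can empty a column; fall back to the max
            bases = frozenset(BASES[int(np.argmax(f[:, i]))])
        out.append(IUPAC_CODES[bases])
    return "".join(out)


def score(matrix: MotifMatrix, window: str) -> float:
    """Additive log-odds score of a window in bits; N contributes 0."""
    if len(window) != matrix.width:
        raise ValueError(
            f"window length {len(window)} != matrix width {matrix.width}"
        )
    codes = encode(window.upper())
    lod = matrix.logodds
    total = 0.0
    for i, c in enumerate(codes):
        if c < 4:
            total += lod[c, i]
    return float(total)


def information_content(matrix: MotifMatrix) -> np.ndarray:
    """Per-position information content IC(i) = 2 + sum_b f log2 f, in bits."""
    f = matrix.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    return 2.0 + plogp.sum(axis=0)


def reverse_complement_matrix(matrix: MotifMatrix) -> MotifMatrix:
    """Reverse positions and complement bases; an involution."""
    return MotifMatrix(
        matrix.counts[::-1, ::-1].copy(),
        alpha=matrix.alpha,
        background=matrix.background[::-1].copy(),
        name=None if matrix.name is None else f"{matrix.name}_rc",
    )


class MotifComparison(NamedTuple):
    offset: int
    orientation: Literal["forward", "reverse"]
    correlation: float
    overlap: int


def _column_pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson r of two frequency 4-vectors; 0 if either has no variance."""
    du, dv = u - u.mean(), v - v.mean()
    nu, nv = np.sqrt((du * du).sum()), np.sqrt((dv * dv).sum())
    if nu == 0 or nv == 0:
        return 0.0
    return float((du * dv).sum() / (nu * nv))


def compare_motifs(
    m1: MotifMatrix, m2: MotifMatrix, min_overlap: int = 4
) -> MotifComparison:
    """Ungapped motif-vs-motif alignment by mean per-column Pearson r.

    Searches every integer offset with at least ``min_overlap`` overlapping
    columns, in both orientations of ``m2`` (reverse = reverse-complemented
    matrix).  Offset d means column j of m2 is aligned with column j + d of
    m1.  The best alignment maximizes the *total* column correlation (the
    sum over overlapping columns, as column-comparison motif aligners do, so
    long consistent overlaps beat short ones); ties go to the larger
    overlap, then the smaller |offset|, then forward orientation.  The
    reported ``correlation`` is the mean over the winning alignment's
    columns.  A column with no variance (e.g. uniform) contributes 0.
    """
    w1, w2 = m1.width, m2.width
    if min_overlap > min(w1, w2):
        raise ValueError(f"min_overlap {min_overlap} > min motif width")
    f1 = m1.freqs
    best: MotifComparison | None = None
    for orientation in ("forward", "reverse"):
        mat = m2 if orientation == "forward" else reverse_complement_matrix(m2)
        f2 = mat.freqs
        for offset in range(-(w2 - min_overlap), w1 - min_overlap + 1):
            lo1, hi1 = max(0, offset), min(w1, offset + w2)
            overlap = hi1 - lo1
            if overlap < min_overlap:
                continue
            cols = [
                _column_pearson(f1[:, i], f2[:, i - offset]) for i in range(lo1, hi1)
            ]
            cand = MotifComparison(offset, orientation, float(np.mean(cols)), overlap)
            if best is None or _comparison_key(cand) > _comparison_key(best):
                best = cand
    assert best is not None
    return best


def _comparison_key(c: MotifComparison) -> tuple:
    return (
        c.correlation * c.overlap,  # total column correlation
        c.overlap,
        -abs(c.offset),
        c.orientation == "forward",
    )


# ---------------------------------------------------------------------------
# Surrogate canonical matrices
# ---------------------------------------------------------------------------


def surrogate_high_matrix(
    *, alpha: float = 1.0, background: Sequence[float] | None = None
) -> MotifMatrix:
    """Surrogate count matrix for the high-affinity motif GTGGCAGT (12 sites).

    The published tabulated matrix is not machine-readable, so this matrix
    encodes its documented structure over 12 aligned high-affinity
    competitor sites: invariant G3, G4, T8 and core T2 (12/12); preferred G1
    (10 G / 2 T, a minority of genuine sites start with T); positions 5 and
    7 restricted to G+C (10 consensus / 2 alternate); position 6 biased to A
    (8/12) with the remainder spread evenly.  Users with a transcription of
    the published matrix can substitute it anywhere a matrix is accepted.
    """
    w = 8
    counts = np.zeros((4, w))

    def put(i: int, **base_counts: float) -> None:
        for b, c in base_counts.items():
            counts[_BASE_INDEX[b], i] = c

    put(0, G=10, T=2)
    put(1, T=12)
    put(2, G=12)
    put(3, G=12)
    put(4, C=10, G=2)
    put(5, A=8, C=4 / 3, G=4 / 3, T=4 / 3)
    put(6, G=10, C=2)
    put(7, T=12)
    return MotifMatrix(counts, alpha=alpha, background=background,
                       name="surrogate_high_GTGGCAGT")


def surrogate_low_matrix(
    *, alpha: float = 1.0, background: Sequence[float] | None = None
) -> MotifMatrix:
    """Surrogate count matrix for the low-affinity motif TGGCACNC (12 sites).

    The low-affinity competitors carry the TGGC core one register to the
    left (motif starts at the core T) and show no preference at position 7,
    modeled as a uniform column so the consensus renders the published 'n'.
    """
    w = 8
    counts = np.zeros((4, w))
    for i, b in enumerate("TGGCAC"):
        counts[_BASE_INDEX[b], i] = 12
    counts[:, 6] = 3  # unconstrained position
    counts[_BASE_INDEX["C"], 7] = 12
    return MotifMatrix(counts, alpha=alpha, background=background,
                       name="surrogate_low_TGGCACNC")


# ---------------------------------------------------------------------------
# Miniature greedy motif discovery
# ---------------------------------------------------------------------------


def discover_motif(
    seqs: Sequence[str],
    width: int = 8,
    max_iter: int = 50,
    seed: int = 0,
    *,
    alpha: float = 1.0,
    background: Sequence[float] | None = None,
) -> MotifMatrix:
    """Greedy one-occurrence-per-sequence motif discovery.

    Every distinct ``width``-mer present in the input seeds a candidate: the
    seed's one-site matrix picks the best-scoring window in each sequence
    (both strands), the matrix is rebuilt from those windows, and the cycle
    repeats until the selected window set is stable or ``max_iter`` is
    reached.  The converged matrix with the highest total log-odds score of
    its selected windows wins; ``seed`` only breaks exact score ties.

    This is a deliberately small stand-in for full EM-based motif discovery
    (MEME-style objectives are out of scope); it reliably recovers a motif
    planted once per sequence.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    seqs = [s.upper() for s in seqs]
    if min(len(s) for s in seqs) < width:
        raise ValueError(f"width {width} exceeds the shortest sequence")
    rng = np.random.default_rng(seed)

    fwd = [s for s in seqs]
    rev = [reverse_complement(s) for s in seqs]
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)

    # precompute window index arrays per sequence/strand
    def windows(s: str) -> np.ndarray:
        codes = encode(s)
        return np.lib.stride_tricks.sliding_window_view(codes, width)

    wf = [windows(s) for s in fwd]
    wr = [windows(s) for s in rev]
    ar = np.arange(width)

    seeds: list[str] = sorted(
        {s[i : i + width] for s in fwd for i in range(len(s) - width + 1)
         if "N" not in s[i : i + width]}
    )

    def best_windows(matrix: MotifMatrix) -> list[tuple[int, int, int]]:
        """Per sequence: (strand 0/1, offset, argmax) of the best window."""
        lod = matrix.logodds
        lod5 = np.vstack([lod, np.zeros((1, width))])  # N row scores 0
        sel = []
        for k in range(len(seqs)):
            sf = lod5[wf[k], ar].sum(axis=1)
            sr = lod5[wr[k], ar].sum(axis=1)
            if sf.max() >= sr.max():  # tie -> plus strand
                sel.append((0, int(np.argmax(sf)), 0))
            else:
                sel.append((1, int(np.argmax(sr)), 0))
        return sel

    def sel_sites(sel: list[tuple[int, int, int]]) -> list[str]:
        out = []
        for k, (strand, off, _) in enumerate(sel):
            src = fwd[k] if strand == 0 else rev[k]
            out.append(src[off : off + width])
        return out

    candidates: list[tuple[float, MotifMatrix]] = []
    for sd in seeds:
        sel = None
        matrix = build_count_matrix([sd], alpha=alpha, background=bg)
        for _ in range(max_iter):
            new_sel = best_windows(matrix)
            if new_sel == sel:
                break
            sel = new_sel
            matrix = build_count_matrix(sel_sites(sel), alpha=alpha, background=bg)
        total = sum(score(matrix, s) for s in sel_sites(sel))
        candidates.append((total, matrix))

    best_total = max(t for t, _ in candidates)
    tied = [m for t, m in candidates if t == best_total]
    chosen = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
    chosen.name = "discovered"
    return chosen


def text_logo(matrix: MotifMatrix) -> str:
    """A small text rendering: consensus plus per-position IC bars."""
    ic = information_content(matrix)
    cons = consensus(matrix)
    bars = "".join(" .:-=+*#"[min(7, int(x / 2 * 7.999))] for x in ic)
    return f"{cons}\n{bars}  (IC per position, 0..2 bits)"
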