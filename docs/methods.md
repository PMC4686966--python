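# Methods

This note documents the models, defaults and design choices behind
`peg3motif`, and what the synthetic-data tests do and do not demonstrate.

## Matrix model

A motif is represented by raw per-position base counts over *N* aligned
sites.  Frequencies are pseudocounted with a total mass α distributed by
the background composition, `f(b,i) = (c(b,i) + α·p(b)) / (N + α)`, and
scores are log2 odds against that background, so a window's score is in
bits and background sequence scores negative on average.  Defaults:

| parameter | default | rationale |
|---|---|---|
| pseudocount α | 1.0 total, background-distributed | one phantom site; keeps zero-count cells finite without drowning a 12-site alignment |
| background p(b) | uniform 0.25 | probe-scale sequences; configurable per-genome (e.g. GC 0.42 for mouse) |
| consensus degeneracy threshold | 0.25 | a base enters the IUPAC set when `f ≥ 0.25`; a fully unconstrained column then renders `N`, matching the `TGGCACnC` notation for the low-affinity motif |
| scan threshold θ | 0.8 of the maximum score | the literature source states no numeric definition of "contains the motif"; this fraction-of-maximum convention is the package's definition, prominently configurable |

The published tabulated matrix is only available as a figure, so the
package ships **surrogate** canonical matrices (12 sites each) encoding the
documented tier structure: high-affinity — invariant T2/G3/G4/T8 (12/12),
preferred G1 (10/2 over T), positions 5 and 7 restricted to G+C (10/2 with
the consensus base favored), position 6 biased to A (8/12, remainder even);
low-affinity — the core shifted one register left (`TGGCAC`, then an
unconstrained column, then C).  The 10/2 minority splits keep minority
frequencies below the 0.25 consensus threshold, so the surrogates render
exactly the published motif strings; a 3/12 minority would sit exactly at
the threshold and widen the consensus to a two-base code.  These cell
values are package decisions, not published data, and any transcription of
the real matrix can be substituted.

## Affinity rules

Classification is anchored on the TGGC core: core at positions 2–5 with G1
and T8 → high; core at 2–5 missing either preference, or core at positions
1–4 (the low-motif register) → low; no core in either register → none.
The rules are a heuristic tier — the competition data include high-affinity
duplexes that violate individual preferences — so genome predictions are
gated by matrix score, not by the classifier.  `count_rule_violations`
counts misses against the critical and G-or-C tiers only (the softer
"preferred" tier is excluded); it is used to tell genuinely motif-like
windows from frame-shifted shadows (below).

Mutation effects are score differences under the matrix; because scoring
is additive, a multi-base effect equals the sum of its single-base effects.

## Scanning and composite sites

Both strands are scanned by scoring every window under the matrix and its
reverse complement; windows containing N are skipped rather than scored at
background (assembly gaps would otherwise accumulate spurious hits).
Score ties at the threshold are included (≥).  Locus-level counting uses
greedy best-score-first selection with same-strand overlap exclusion.

A composite site is a pair of hits on one record with a gap (end of the
left hit to start of the right hit, half-open coordinates) between 0 and
`max_spacer` (default 20 bp); "4 bp apart" therefore means gap = 4.
Overlapping occurrences are not paired, and opposite orientation means
strand inequality — convergent vs divergent geometry is reported as
metadata but not used for classification.

**Partner admission.**  Genuine second sites can be weak (the known paired
probe's second motif scores below 0 bits under the high-affinity matrix),
so the partner scan threshold may be set below zero as a fraction of the
maximum score.  At such permissive thresholds, frame-shifted windows
overlapping a strong site ("shadows") can outscore a genuine weak partner,
because a shift can trade core mismatches for an accidental T8 match.  The
detector therefore optionally filters hits by rule compatibility
(`max_rule_violations`, counting critical and G-or-C misses): the genuine
weak partner violates only T8 (1 violation) while its shadows violate core
positions (≥ 2), so a cutoff of 1 isolates the printed register.  This
rule-gated admission is the package's design for permissive partner scans;
at ordinary thresholds (θ ≥ 0.6) it is unnecessary and off by default.

## Peak annotation

The source study names categories (promoter, 5'/3' enhancer, intronic
enhancer, intergenic) but states no window sizes, so the operational
definitions are package defaults, all configurable: promoter =
TSS − 1000 .. TSS + 500 in gene orientation; 5'/3' enhancer = the 10-kb
flank upstream of the promoter window / downstream of the TES; intronic
categories require intron overlap, with the first intron distinguished.
Precedence for multi-category overlaps is promoter > intron > 5' flank >
3' flank; across genes the best category wins, with ties broken by smaller
|TSS distance| and then gene name, making annotation invariant to gene-file
row order.  Peaks overlapping only exons fall through to the flank tests —
an "exonic" category is deliberately not distinguished because the
published vocabulary has none.

## Validation arithmetic

Relative expression uses the Livak method: per sample group,
ΔCt = mean Ct(target) − mean Ct(reference) over replicates; ΔΔCt subtracts
the calibrator group's ΔCt; fold = 2^−ΔΔCt.  The standard error adds the
four replicate variances of means (target/reference × test/calibrator) and
is propagated to the fold scale by the delta method
(`se_fold = ln2 · fold · se_ΔΔCt`).  Reported errors are not compared to
published values (none are printed); they calibrate the synthetic recovery
tests.  Amplification-efficiency correction (Pfaffl) is out of scope.

The digest model cuts after a fixed offset within every non-overlapping
recognition-site occurrence found left to right (PvuII: CAGCTG, blunt cut
after 3 — standard enzymology supplied by the built-in enzyme table).
Allele calls compare band patterns as *sets* of fragment lengths, because
co-migrating fragments from different alleles merge on a gel; every
minimal allele subset whose expected bands equal the observation is
returned, and an unexplainable pattern is an error.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their seed and parameters.

* **Genomes** are i.i.d. bases at GC 0.42 (mouse-like).  Real genomes have
  repeats, CpG islands and compositional heterogeneity; recovery results
  here bound performance under a *neutral* background only.
* **Planting** overwrites bases in place (coordinates stay stable) with
  sites sampled from a matrix under a temperature parameter: 0 → consensus
  only (used by the recovery tests, where 100% recall is then guaranteed by
  construction and tests the machinery, not the statistics), 1 → the
  matrix frequencies.  Composite planting draws a spacer and
  reverse-complements the second member with probability
  `opposite_fraction`.  Placements keep ≥ 200 bp apart so planted sites
  never pair with each other accidentally.
* **Competitor panels** construct the high register and two low forms
  (shifted core; lost G1/T8) directly, so label accuracy is 100% at zero
  mutation rate by construction; a mutation rate degrades it, which the
  tests assert as an inequality only.
* **Ct tables** hold the reference gene at a constant baseline and shift
  the test group's target Ct by −log2(fold) plus Gaussian noise per well
  (default sd 0.2 cycles, 3 replicates — plausible qPCR practice; the
  source reports neither).  Recovery of the fold panel {2.5, 5.5, 1.5,
  4.0} is exact at zero noise by inversion.

Problem sizes in the test suite — a 1-Mb genome with 50 singles and 10
composites for genome-scale recovery, 100 × 10-kb sequences for
scanner/oracle parity, 500 seeds for fold-change bias — were chosen as the
smallest sizes at which the checks are statistically meaningful.

## Known limitations

* The surrogate matrices stand in for unpublished cell values; absolute
  scores and the genome-wide occurrence count depend on them and on the
  θ = 0.8 convention, so no attempt is made to reproduce the reported
  ~84,000 mm9 loci (threshold definition unstated; whole-genome input
  out of scope).
* Motif discovery is a deliberately small greedy one-occurrence-per-
  sequence procedure, not an EM over a ZOOPS/OOPS likelihood; it recovers
  a motif planted once per sequence but has no significance model.
* The affinity classifier is rule-based and ignores energetics; it is not
  a predictor of gel-shift band intensity.
* Enhancer calls are purely positional; histone-mark evidence is not
  integrated.
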