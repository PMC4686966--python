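"""Computational readouts of the wet-lab validation experiments.

Two independent pieces of arithmetic back the expression-validation stage:

* relative expression by the Livak 2^-ddCt method with an internal-control
  gene (beta-actin in the source experiments), replicate-mean dCt per
  sample group and first-order (delta-method) error propagation;
* an in-silico restriction digest plus an allele-call rule for the
  PvuII-based imprinting readout, where the fragment pattern of an RT-PCR
  product distinguishes the two parental alleles of an F1 hybrid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

#: Recognition site and blunt cut offset of common enzymes used here.
ENZYMES = {
    "PvuII": ("CAGCTG", 3),
    "EcoRV": ("GATATC", 3),
}

CT_COLUMNS = ["group", "tissue", "gene", "replicate", "ct"]


@dataclass(frozen=True)
class FoldChangeResult:
    """Relative expression of one gene in one tissue, test vs calibrator."""

    gene: str
    tissue: str
    group: str  # the test group (e.g. KO)
    fold_change: float  # 2^-ddCt, > 0
    log2_fold_change: float
    se_log2: float  # sd of ddCt propagated from replicate variances
    se: float  # delta-method se of the fold change itself


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycles")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
) -> list[FoldChangeResult]:
    """Livak relative quantification over a long-format Ct table.

    Per (tissue, group): dCt(gene) = mean Ct(gene) - mean Ct(reference).
    Per (tissue, test group, gene): ddCt = dCt(test) - dCt(calibrator) and
    fold = 2^-ddCt.  The standard error combines the replicate variances of
    target and reference in both groups (variances of means added).
    """
    table = _validate_ct_table(table)
    groups = sorted(table["group"].unique())
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} absent from table")
    if len(groups) < 2:
        raise ValueError("need at least one test group besides the calibrator")

    stats = (
        table.groupby(["tissue", "group", "gene"])["ct"]
        .agg(["mean", "var", "count"])
        .reset_index()
    )
    results: list[FoldChangeResult] = []
    for tissue, tissue_stats in stats.groupby("tissue"):
        by_group = {g: df.set_index("gene") for g, df in tissue_stats.groupby("group")}
        for g, df in by_group.items():
            if reference_gene not in df.index:
                raise ValueError(
                    f"reference gene {reference_gene!r} missing in group {g!r},"
                    f" tissue {tissue!r}"
                )
        cal = by_group[calibrator_group]
        for test_group in groups:
            if test_group == calibrator_group:
                continue
            test = by_group[test_group]
            for gene in test.index:
                if gene == reference_gene or gene not in cal.index:
                    continue
                ddct = (
                    (test.loc[gene, "mean"] - test.loc[reference_gene, "mean"])
                    - (cal.loc[gene, "mean"] - cal.loc[reference_gene, "mean"])
                )
                var = 0.0
                for df, idx in (
                    (test, gene), (test, reference_gene),
                    (cal, gene), (cal, reference_gene),
                ):
                    v, n = df.loc[idx, "var"], df.loc[idx, "count"]
                    if n > 1 and not math.isnan(v):
                        var += v / n
                fold = 2.0 ** (-ddct)
                se_log2 = math.sqrt(var)
                results.append(
                    FoldChangeResult(
                        gene=gene,
                        tissue=str(tissue),
                        group=test_group,
                        fold_change=fold,
                        log2_fold_change=-ddct,
                        se_log2=se_log2,
                        se=math.log(2) * fold * se_log2,
                    )
                )
    results.sort(key=lambda r: (r.tissue, r.group, r.gene))
    return results


def fold_changes_frame(results: Sequence[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def digest(
    seq: str,
    recognition_site: str = "CAGCTG",
    cut_offset: int = 3,
) -> list[int]:
    """Fragment lengths after cutting at every non-overlapping site.

    Sites are located left to right; each cut falls after ``cut_offset``
    bases of the site.  A site-free sequence yields a single fragment; the
    fragment lengths always sum to the sequence length.
    """
    if not 0 <= cut_offset <= len(recognition_site):
        raise ValueError("cut_offset outside the recognition site")
    seq = seq.upper()
    site = recognition_site.upper()
    cuts: list[int] = []
    k = seq.find(site)
    while k != -1:
        cuts.append(k + cut_offset)
        k = seq.find(site, k + len(site))  # non-overlapping
    edges = [0, *cuts, len(seq)]
    return sorted(e2 - e1 for e1, e2 in zip(edges, edges[1:]))


def digest_with_enzyme(seq: str, enzyme: str) -> list[int]:
    """Digest with a named enzyme from the built-in table."""
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; known: {sorted(ENZYMES)}")
    site, offset = ENZYMES[enzyme]
    return digest(seq, site, offset)


def allele_call(
    observed_fragments: Sequence[int],
    allele_profiles: Mapping[str, Sequence[int]],
) -> list[frozenset[str]]:
    """Minimal allele subsets whose band pattern explains the observation.

    Band patterns are compared as sets of fragment lengths (co-migrating
    fragments from different alleles merge on a gel).  Every minimal subset
    whose union of expected bands equals the observed bands is returned; a
    single-element subset is a monoallelic call.  Raises if no subset
    explains the observation.
    """
    observed = frozenset(observed_fragments)
    if not observed:
        raise ValueError("no observed fragments")
    names = sorted(allele_profiles)
    explanations: list[frozenset[str]] = []
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            bands: set[int] = set()
            for a in combo:
                bands.update(allele_profiles[a])
            if frozenset(bands) == observed:
                subset = frozenset(combo)
                if not any(prev < subset for prev in explanations):
                    explanations.append(subset)
    if not explanations:
        raise ValueError(
            f"inconsistent digest: bands {sorted(observed)} explained by no "
            f"subset of alleles {names}"
        )
    return explanations
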