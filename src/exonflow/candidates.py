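"""Candidate-gene selection: primary list, sub-lists A/B/C, and the
filter diagnostic.

From the splicing-ANOVA results a primary list is drawn at an FDR level on
the interaction p-value.  Three sub-lists focus it for manual inspection:

* A - differential splicing without differential gene expression
      (pathology group p > 0.05), top genes by most extreme SI;
* B - differential splicing with differential gene expression (group
      p <= 0.05), patient-homogeneous (patient p > 0.2), gene fold-change
      not exceeding the splicing index, top genes by most extreme SI;
* C - genes whose probe sets overlap a catalogued alternative-splicing
      event (UCSC knownAlt schema) with SI >= 1.4 or <= 1/1.4.

The final list is the union A | B | C.  The delta-log-p diagnostic
quantifies how strongly the background filter shifts p-values of the genes
it adds or removes (sample skewness plus the D'Agostino skewness test).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "read_known_alt",
    "primary_list",
    "sublist_A",
    "sublist_B",
    "sublist_C",
    "final_list",
    "CandidateLists",
    "select_candidates",
    "delta_logp_diagnostic",
]


def read_known_alt(path: str | Path) -> pd.DataFrame:
    """Read a UCSC knownAlt-schema TSV (bin, chrom, chromStart, chromEnd,
    name, score, strand)."""
    df = pd.read_csv(path, sep="\t")
    if "chromStart" not in df.columns:  # headerless export
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["bin", "chrom", "chromStart", "chromEnd", "name", "score", "strand"],
        )
    return df


def primary_list(results, fdr: float = 0.05) -> tuple[list[str], float | None]:
    """Genes significant at the FDR level, sorted by interaction p-value.

    Returns (gene ids, realized p threshold)."""
    gt = results.gene_table
    sig = gt[gt["q_AS"] <= fdr].reset_index().sort_values(["p_AS", "gene"])
    return list(sig["gene"]), results.p_threshold


def sublist_A(results, top: int = 100, fdr: float = 0.05) -> list[str]:
    """Splicing without differential gene expression: primary-list genes
    with pathology-group p > 0.05, top ``top`` by most extreme SI."""
    primary, _ = primary_list(results, fdr)
    gt = results.gene_table.loc[primary].reset_index()
    keep = gt[gt["p_G"] > 0.05]
    ranked = keep.sort_values(["max_abs_log2_si", "gene"], ascending=[False, True])
    return list(ranked["gene"].head(top))


def sublist_B(results, top: int = 100, fdr: float = 0.05) -> list[str]:
    """Splicing on top of differential expression: primary-list genes with
    group p <= 0.05, patient p > 0.2, and |log2 gene FC| <= max |log2 SI|,
    top ``top`` by most extreme SI."""
    primary, _ = primary_list(results, fdr)
    gt = results.gene_table.loc[primary].reset_index()
    keep = gt[
        (gt["p_G"] <= 0.05)
        & (gt["p_P"] > 0.2)
        & (gt["cg_gene"].abs() <= gt["max_abs_log2_si"])
    ]
    ranked = keep.sort_values(["max_abs_log2_si", "gene"], ascending=[False, True])
    return list(ranked["gene"].head(top))


def sublist_C(
    results,
    known_alt: pd.DataFrame,
    probeset_coords: pd.DataFrame,
    *,
    si_thresh: float = 1.4,
    fdr: float = 0.05,
    scope: str = "primary",
    stranded: bool = True,
) -> list[str]:
    """Genes whose catalogued-AS probe sets show an extreme splicing index.

    A probe set overlaps a known event when their intervals intersect by at
    least one base (strand-aware by default); the gene is included when any
    such probe set has SI >= ``si_thresh`` or <= 1/``si_thresh``.  By
    default the search is restricted to the primary list
    (``scope='all'`` lifts the restriction).
    """
    if scope not in ("primary", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    trees: dict[tuple, IntervalTree] = {}
    for row in known_alt.itertuples(index=False):
        start, end = int(row.chromStart), int(row.chromEnd)
        if start >= end:
            continue
        keys = [(row.chrom, row.strand)] if stranded else [(row.chrom, None)]
        for key in keys:
            trees.setdefault(key, IntervalTree())[start:end] = row.name

    if scope == "primary":
        allowed = set(primary_list(results, fdr)[0])
    else:
        allowed = set(results.gene_table.index)

    pt = results.probeset_table
    coords = probeset_coords.set_index("probeset_id")
    hits: set[str] = set()
    for ps, row in pt.iterrows():
        gene = row["gene"]
        if gene not in allowed or ps not in coords.index:
            continue
        c = coords.loc[ps]
        key = (c["chrom"], c["strand"]) if stranded else (c["chrom"], None)
        tree = trees.get(key)
        if tree is None or not tree.overlap(int(c["start"]), int(c["end"])):
            continue
        si = row["si"]
        if si >= si_thresh or si <= 1.0 / si_thresh:
            hits.add(gene)
    return sorted(hits)


@dataclass
class CandidateLists:
    primary: list[str]
    p_threshold: float | None
    A: list[str]
    B: list[str]
    C: list[str]

    @property
    def final(self) -> list[str]:
        return sorted(set(self.A) | set(self.B) | set(self.C))

    def venn_counts(self) -> dict[str, int]:
        a, b, c = set(self.A), set(self.B), set(self.C)
        return {
            "A_only": len(a - b - c),
            "B_only": len(b - a - c),
            "C_only": len(c - a - b),
            "AB": len((a & b) - c),
            "AC": len((a & c) - b),
            "BC": len((b & c) - a),
            "ABC": len(a & b & c),
            "total": len(a | b | c),
        }

    def membership_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "in_A": g in set(self.A),
                "in_B": g in set(self.B),
                "in_C": g in set(self.C),
            }
            for g in self.final
        ]
        return pd.DataFrame(rows)


def final_list(A: list[str], B: list[str], C: list[str]) -> CandidateLists:
    """Assemble the union of the sub-lists with Venn region counts."""
    return CandidateLists(primary=[], p_threshold=None, A=list(A), B=list(B), C=list(C))


def select_candidates(
    results,
    known_alt: pd.DataFrame,
    probeset_coords: pd.DataFrame,
    *,
    fdr: float = 0.05,
    top: int = 100,
    si_thresh: float = 1.4,
) -> CandidateLists:
    """Run the full candidate-selection stage."""
    primary, threshold = primary_list(results, fdr)
    return CandidateLists(
        primary=primary,
        p_threshold=threshold,
        A=sublist_A(results, top, fdr),
        B=sublist_B(results, top, fdr),
        C=sublist_C(results, known_alt, probeset_coords, si_thresh=si_thresh, fdr=fdr),
    )


def delta_logp_diagnostic(
    p_without_filter: pd.Series,
    p_with_filter: pd.Series,
) -> tuple[float, float]:
    """Skewness diagnostic of filter-induced p-value shifts.

    For each gene in both inputs, delta log p = log(p with filter) -
    log(p without filter); returns (bias-corrected sample skewness,
    D'Agostino skewness-test p-value).  At least eight genes are required
    for the test to be defined.
    """
    common = p_without_filter.index.intersection(p_with_filter.index)
    delta = np.log(p_with_filter.loc[common].to_numpy(dtype=float)) - np.log(
        p_without_filter.loc[common].to_numpy(dtype=float)
    )
    delta = delta[np.isfinite(delta)]
    if delta.size < 8:
        raise ValueError("skewness test needs at least 8 observations")
    g1 = float(stats.skew(delta, bias=False))
    stat, p = stats.skewtest(delta)
    return g1, float(p)
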