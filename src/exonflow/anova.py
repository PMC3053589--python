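"""Mixed-model splicing ANOVA and splicing indices.

Per gene, the log2 probe-set x sample expression block is analysed with the
split-plot mixed linear model

    I = mu + G + P + E + E*G + S(G*P) + eps

where G is the pathology group (tumour/NAT, or AdCa/SCC/NAT in subtype
mode), P the random patient factor, E the exon (probe set) factor, and
S(G*P) the sample-to-sample random factor nested in group and patient.
Whole-plot effects (G, P) are tested against the sample stratum MS and
within-sample effects (E, E*G) against the residual MS; on the balanced
matched-pair design this is the exact expected-mean-square ANOVA, and on
unbalanced data each term is tested as its Type-III-style increment
R(term | other terms) in its stratum.

Per probe set, the reduced model I = mu + G + P + eps provides the
pathology-group contrast cg (tumour - NAT adjusted for patient); the
splicing index of a probe set is the contrast relative to its gene,
log2 SI = cg_exon - cg_gene, reported also as the linear ratio 2**log2SI.
Benjamini-Hochberg controls the FDR over the per-gene interaction
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneFit",
    "Contrast",
    "fit_gene_mlm",
    "fit_probeset_mlm",
    "splicing_index",
    "bh_fdr",
    "SplicingAnova",
    "SplicingAnovaResults",
    "run_splicing_analysis",
]

_P_FLOOR = 1e-300


class DesignError(ValueError):
    """Deficient design (e.g. a single patient or a single group)."""


# ---------------------------------------------------------------------------
# linear-algebra helpers
# ---------------------------------------------------------------------------

def _basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0:
        return u[:, :0]
    rank = int((s > s[0] * 1e-10).sum())
    return u[:, :rank]


def _ssr(y: np.ndarray, Q: np.ndarray) -> float:
    """Residual sum of squares of y against the column space basis Q."""
    proj = Q.T @ y
    return float(y @ y - proj @ proj)


def _dummies(labels: pd.Series | np.ndarray) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(dtype=float)


def _f_pvalue(
    ss_num: float, df_num: int, ss_den: float, df_den: int, tol: float = 1e-12
) -> float:
    """F-test p-value with degenerate-variance handling.

    A numerator SS of (numerically) zero cannot indicate an effect -> p = 1;
    a zero denominator under a non-zero numerator is infinite evidence.
    ``tol`` should be scaled to the data (roundoff in the projections is
    relative to the total sum of squares, not absolute).
    """
    if df_num <= 0 or df_den <= 0:
        return 1.0
    if ss_num <= tol:
        return 1.0
    if ss_den <= tol:
        return _P_FLOOR
    f = (ss_num / df_num) / (ss_den / df_den)
    return float(max(stats.f.sf(f, df_num, df_den), _P_FLOOR))


# ---------------------------------------------------------------------------
# per-gene mixed model
# ---------------------------------------------------------------------------

@dataclass
class GeneFit:
    """ANOVA table of one gene's split-plot mixed model."""

    p_AS: float
    p_G: float
    p_P: float
    ss: dict[str, float]
    df: dict[str, int]

    @property
    def ms(self) -> dict[str, float]:
        return {k: self.ss[k] / self.df[k] for k in self.ss if self.df[k] > 0}


def _check_design(design: pd.DataFrame, group_col: str) -> None:
    if design[group_col].nunique() < 2:
        raise DesignError("factor 'group' has fewer than two levels")
    if design["patient"].nunique() < 2:
        raise DesignError("factor 'patient' has fewer than two levels")


class _GeneDesignBases:
    """Cached orthonormal bases for a (design, n_exons) combination.

    All projections in the split-plot fit depend only on the sample order,
    the group and patient labels, and the number of exons; caching them
    makes repeated fits over the same design (a whole chip, or a
    simulation) cheap.
    """

    _cache: dict[tuple, "_GeneDesignBases"] = {}

    def __init__(self, groups: tuple, patients: tuple, k: int) -> None:
        n_s = len(groups)
        G = _dummies(np.array(groups))
        P = _dummies(np.array(patients))
        ones = np.ones((n_s, 1))
        self.Q_full = _basis(np.hstack([ones, G, P]))
        self.Q_noG = _basis(np.hstack([ones, P]))
        self.Q_noP = _basis(np.hstack([ones, G]))
        exon = np.repeat(np.arange(k), n_s)
        sample_idx = np.tile(np.arange(n_s), k)
        S = _dummies(sample_idx)
        E = _dummies(exon)
        eg = np.array([f"{e}|{groups[s]}" for e, s in zip(exon, sample_idx)])
        EG = _dummies(eg)
        self.Q_s = _basis(S)
        self.Q_se = _basis(np.hstack([S, E]))
        self.Q_seg = _basis(np.hstack([S, E, EG]))

    @classmethod
    def get(cls, groups: tuple, patients: tuple, k: int) -> "_GeneDesignBases":
        key = (groups, patients, k)
        if key not in cls._cache:
            if len(cls._cache) > 64:
                cls._cache.clear()
            cls._cache[key] = cls(groups, patients, k)
        return cls._cache[key]


def fit_gene_mlm(
    block: pd.DataFrame,
    design: pd.DataFrame,
    *,
    group_col: str = "pathology",
) -> GeneFit:
    """Fit the per-gene split-plot model and return its ANOVA table.

    ``block`` holds log2 expression, rows = probe sets (exons), columns =
    samples; ``design`` maps samples to patient and group.  The
    exon-by-group interaction (the alternative-splicing effect) and the
    exon main effect are tested against the residual MS; group and patient
    are tested in the whole-plot (per-sample mean) stratum against the
    sample-to-sample MS.
    """
    design = design.set_index("sample").loc[list(block.columns)].reset_index()
    _check_design(design, group_col)
    k, n_s = block.shape
    if k < 2:
        raise DesignError("gene model needs at least two probe sets")

    groups = tuple(design[group_col])
    patients = tuple(design["patient"])
    bases = _GeneDesignBases.get(groups, patients, k)

    # --- whole-plot stratum: per-sample means, model  mean ~ G + P
    y_wp = block.to_numpy(dtype=float).mean(axis=0)
    Q_full, Q_noG, Q_noP = bases.Q_full, bases.Q_noG, bases.Q_noP
    rank_full = Q_full.shape[1]
    df_wp_resid = n_s - rank_full
    if df_wp_resid <= 0:
        raise DesignError(
            "sample stratum saturated: factor 'patient' leaves no degrees of "
            "freedom to test group and patient effects"
        )
    # whole-plot SS on the raw scale = k * SS on the means scale
    sse_wp = k * _ssr(y_wp, Q_full)
    ss_G = k * (_ssr(y_wp, Q_noG) - _ssr(y_wp, Q_full))
    ss_P = k * (_ssr(y_wp, Q_noP) - _ssr(y_wp, Q_full))
    df_G = rank_full - Q_noG.shape[1]
    df_P = rank_full - Q_noP.shape[1]

    # --- subplot stratum: full data, sample factor absorbs mu+G+P+S(G*P)
    y = block.to_numpy(dtype=float).ravel(order="C")  # exon-major
    Q_s, Q_se, Q_seg = bases.Q_s, bases.Q_se, bases.Q_seg
    sse = _ssr(y, Q_seg)
    df_resid = y.size - Q_seg.shape[1]
    ss_E = _ssr(y, Q_s) - _ssr(y, Q_se)
    df_E = Q_se.shape[1] - Q_s.shape[1]
    ss_EG = _ssr(y, Q_se) - _ssr(y, Q_seg)
    df_EG = Q_seg.shape[1] - Q_se.shape[1]

    # roundoff in the projections scales with the centred total SS
    ss_tot = float(((y - y.mean()) ** 2).sum())
    tol = max(1e-12, 1e-10 * ss_tot)
    p_AS = _f_pvalue(ss_EG, df_EG, sse, df_resid, tol)
    p_G = _f_pvalue(ss_G, df_G, sse_wp, df_wp_resid, tol)
    p_P = _f_pvalue(ss_P, df_P, sse_wp, df_wp_resid, tol)
    return GeneFit(
        p_AS=p_AS,
        p_G=p_G,
        p_P=p_P,
        ss={
            "G": ss_G, "P": ss_P, "E": ss_E, "E:G": ss_EG,
            "S(G*P)": sse_wp, "residual": sse,
        },
        df={
            "G": df_G, "P": df_P, "E": df_E, "E:G": df_EG,
            "S(G*P)": df_wp_resid, "residual": df_resid,
        },
    )


# ---------------------------------------------------------------------------
# per-probe-set model and contrasts
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    """Pathology-group contrast from the reduced model I = mu + G + P + eps."""

    cg: float          # log2 tumour - NAT difference, patient-adjusted
    p_G: float
    p_P: float
    scope: str = "probe_set"


def fit_probeset_mlm(
    values: pd.Series,
    design: pd.DataFrame,
    *,
    group_col: str = "pathology",
    tumour_level: str = "tumour",
    nat_level: str = "NAT",
) -> Contrast:
    """Patient-adjusted tumour-NAT contrast of one probe set (or gene).

    Ordinary least squares on I = mu + G + P + eps; on balanced paired data
    the contrast equals the mean per-patient tumour - NAT difference.
    """
    design = design.set_index("sample").loc[list(values.index)].reset_index()
    _check_design(design, group_col)
    y = values.to_numpy(dtype=float)
    n = y.size
    g = (design[group_col].to_numpy() == tumour_level).astype(float)
    if g.sum() == 0 or g.sum() == n:
        raise DesignError("all samples in one group; contrast undefined")
    P = _dummies(design["patient"])
    ones = np.ones((n, 1))
    X = np.hstack([ones, g[:, None], P[:, 1:]])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    cg = float(beta[1])

    Q_full = _basis(X)
    Q_noG = _basis(np.hstack([ones, P[:, 1:]]))
    Q_noP = _basis(np.hstack([ones, g[:, None]]))
    sse = _ssr(y, Q_full)
    df_resid = n - Q_full.shape[1]
    ss_G = _ssr(y, Q_noG) - sse
    ss_P = _ssr(y, Q_noP) - sse
    tol = max(1e-12, 1e-10 * float(((y - y.mean()) ** 2).sum()))
    p_G = _f_pvalue(ss_G, Q_full.shape[1] - Q_noG.shape[1], sse, df_resid, tol)
    p_P = _f_pvalue(ss_P, Q_full.shape[1] - Q_noP.shape[1], sse, df_resid, tol)
    return Contrast(cg=cg, p_G=p_G, p_P=p_P)


def splicing_index(cg_exon: float, cg_gene: float) -> tuple[float, float]:
    """Splicing index of an exon relative to its gene.

    Both contrasts are log2 fold-changes; returns (log2_si, si_linear)
    where log2_si = cg_exon - cg_gene and si_linear = 2**log2_si, the ratio
    of the exon's linear fold-change to the gene's.
    """
    log2_si = cg_exon - cg_gene
    return log2_si, float(2.0 ** log2_si)


def bh_fdr(pvals, fdr: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg q-values and the realized p-value threshold.

    Returns (q, threshold) where threshold is the largest p with q <= fdr
    (None when nothing is significant).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), None
    _, q, _, _ = multipletests(p, method="fdr_bh")
    passing = p[q <= fdr]
    threshold = float(passing.max()) if passing.size else None
    return q, threshold


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class SplicingAnovaResults:
    """Results of a differential-splicing analysis.

    ``gene_table`` has one row per gene (transcript cluster) with the ANOVA
    p-values, BH q-value, the gene-level contrast and fold-change, and the
    extreme-SI ranking key; ``probeset_table`` has one row per probe set
    with its contrast and splicing index (per subtype in subtype mode).
    """

    gene_table: pd.DataFrame
    probeset_table: pd.DataFrame
    mode: str
    fdr: float
    p_threshold: float | None
    subtype_delta_threshold: float = 0.5

    def summary(self) -> str:
        lines = [
            "Differential-splicing ANOVA",
            "===========================",
            f"mode:                 {self.mode}",
            f"genes analysed:       {len(self.gene_table)}",
            f"probe sets analysed:  {len(self.probeset_table)}",
            f"FDR level:            {self.fdr}",
            f"realized p threshold: "
            + (f"{self.p_threshold:.4g}" if self.p_threshold is not None else "none"),
            f"significant genes:    {int((self.gene_table['q_AS'] <= self.fdr).sum())}",
        ]
        if self.mode == "subtype":
            n_flag = int(self.probeset_table["subtype_specific"].sum())
            lines.append(f"subtype-specific probe sets (|dlog2 SI| >= "
                         f"{self.subtype_delta_threshold}): {n_flag}")
        top = self.gene_table.nsmallest(min(10, len(self.gene_table)), "p_AS")
        lines.append("")
        lines.append(top.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gene_table.to_csv(outdir / "genes.tsv", sep="\t")
        self.probeset_table.to_csv(outdir / "probe_sets.tsv", sep="\t")


class SplicingAnova:
    """Differential-splicing model over a filtered expression data set.

    Parameters
    ----------
    expr_probeset : DataFrame
        log2 probe-set x sample expression.
    expr_gene : DataFrame
        log2 gene x sample expression (Tukey-biweight summaries); the
        gene-level contrast is estimated from this matrix.
    design : DataFrame
        columns sample, patient, pathology (tumour/NAT) and, for subtype
        mode, subtype (AdCa/SCC).
    probeset_to_gene : mapping
        probe set id -> gene (transcript cluster) id.
    mode : {"pathology", "subtype"}
    min_probe_sets : int
        genes with fewer probe sets are excluded before fitting.
    """

    def __init__(
        self,
        expr_probeset: pd.DataFrame,
        expr_gene: pd.DataFrame,
        design: pd.DataFrame,
        probeset_to_gene: Mapping[str, str],
        *,
        mode: str = "pathology",
        min_probe_sets: int = 5,
    ) -> None:
        if mode not in ("pathology", "subtype"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "subtype" and "subtype" not in design.columns:
            raise DesignError("subtype mode requires a 'subtype' design column")
        self.expr_probeset = expr_probeset
        self.expr_gene = expr_gene
        self.design = design.copy()
        self.probeset_to_gene = dict(probeset_to_gene)
        self.mode = mode
        self.min_probe_sets = min_probe_sets
        self.subtype_delta_threshold = 0.5

    @classmethod
    def from_chipdef(cls, expr_probeset, expr_gene, design, chipdef, **kw):
        return cls(expr_probeset, expr_gene, design, chipdef.probeset_to_cluster(), **kw)

    # -- internals ---------------------------------------------------------

    def _gene_blocks(self):
        by_gene: dict[str, list[str]] = {}
        for ps in self.expr_probeset.index:
            gene = self.probeset_to_gene.get(ps)
            if gene is not None:
                by_gene.setdefault(gene, []).append(ps)
        for gene in sorted(by_gene):
            members = by_gene[gene]
            if len(members) >= self.min_probe_sets:
                yield gene, members

    def _anova_design(self) -> pd.DataFrame:
        design = self.design
        if self.mode == "subtype":
            design = design.copy()
            design["group"] = np.where(
                design["pathology"] == "NAT", "NAT", design["subtype"]
            )
            return design
        design = design.copy()
        design["group"] = design["pathology"]
        return design

    def _subtype_subsets(self) -> dict[str, pd.DataFrame]:
        out = {}
        for st in sorted(self.design.loc[self.design["pathology"] == "tumour", "subtype"].unique()):
            patients = self.design.loc[
                (self.design["subtype"] == st), "patient"
            ].unique()
            out[st] = self.design[self.design["patient"].isin(patients)]
        return out

    # -- fitting -----------------------------------------------------------

    def fit(self, fdr: float = 0.05) -> SplicingAnovaResults:
        design = self._anova_design()
        gene_rows = []
        ps_rows = []
        subsets = self._subtype_subsets() if self.mode == "subtype" else None

        for gene, members in self._gene_blocks():
            block = self.expr_probeset.loc[members]
            gfit = fit_gene_mlm(block, design, group_col="group")
            if gene in self.expr_gene.index:
                gvalues = self.expr_gene.loc[gene]
            else:
                gvalues = block.mean(axis=0)
            g_contrast = fit_probeset_mlm(gvalues, self.design)
            row = {
                "gene": gene,
                "n_probe_sets": len(members),
                "p_AS": gfit.p_AS,
                "p_G": gfit.p_G,
                "p_P": gfit.p_P,
                "cg_gene": g_contrast.cg,
                "fc_gene": 2.0 ** g_contrast.cg,
            }
            max_abs = 0.0
            for ps in members:
                c = fit_probeset_mlm(self.expr_probeset.loc[ps], self.design)
                log2_si, si = splicing_index(c.cg, g_contrast.cg)
                ps_row = {
                    "probe_set": ps,
                    "gene": gene,
                    "cg": c.cg,
                    "log2_si": log2_si,
                    "si": si,
                }
                if subsets is not None:
                    per_st = {}
                    for st, sub in subsets.items():
                        samples = [s for s in sub["sample"] if s in self.expr_probeset.columns]
                        c_st = fit_probeset_mlm(
                            self.expr_probeset.loc[ps, samples], sub
                        )
                        g_st = fit_probeset_mlm(gvalues[samples], sub)
                        l2, si_st = splicing_index(c_st.cg, g_st.cg)
                        ps_row[f"cg_{st}"] = c_st.cg
                        ps_row[f"log2_si_{st}"] = l2
                        ps_row[f"si_{st}"] = si_st
                        per_st[st] = l2
                    if {"AdCa", "SCC"} <= set(per_st):
                        delta = per_st["AdCa"] - per_st["SCC"]
                        ps_row["delta_log2_si"] = delta
                        ps_row["subtype_specific"] = abs(delta) >= self.subtype_delta_threshold
                ps_rows.append(ps_row)
                max_abs = max(max_abs, abs(log2_si))
            row["max_abs_log2_si"] = max_abs
            gene_rows.append(row)

        gene_table = pd.DataFrame(gene_rows).set_index("gene") if gene_rows else pd.DataFrame(
            columns=["n_probe_sets", "p_AS", "p_G", "p_P", "cg_gene", "fc_gene",
                     "max_abs_log2_si"]
        )
        if len(gene_table):
            q, threshold = bh_fdr(gene_table["p_AS"].to_numpy(), fdr)
            gene_table["q_AS"] = q
        else:
            threshold = None
            gene_table["q_AS"] = []
        probeset_table = (
            pd.DataFrame(ps_rows).set_index("probe_set") if ps_rows else pd.DataFrame()
        )
        return SplicingAnovaResults(
            gene_table=gene_table,
            probeset_table=probeset_table,
            mode=self.mode,
            fdr=fdr,
            p_threshold=threshold,
            subtype_delta_threshold=self.subtype_delta_threshold,
        )


def run_splicing_analysis(
    expr_probeset: pd.DataFrame,
    expr_gene: pd.DataFrame,
    design: pd.DataFrame,
    probeset_to_gene: Mapping[str, str],
    *,
    mode: str = "pathology",
    fdr: float = 0.05,
    min_probe_sets: int = 5,
) -> SplicingAnovaResults:
    """Functional wrapper: build a :class:`SplicingAnova` and fit it."""
    model = SplicingAnova(
        expr_probeset, expr_gene, design, probeset_to_gene,
        mode=mode, min_probe_sets=min_probe_sets,
    )
    return model.fit(fdr=fdr)
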