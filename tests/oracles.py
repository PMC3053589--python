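"""Independent reference implementations used as test oracles.

These deliberately avoid the projection machinery of ``exonflow.anova``:
the balanced split-plot sums of squares are computed from the classical
cell-mean formulas, and the unbalanced ones from explicit dummy-matrix
least squares.
"""

import numpy as np
import pandas as pd


def balanced_splitplot_ss(block: pd.DataFrame, design: pd.DataFrame,
                          group_col: str = "pathology") -> dict:
    """Classical cell-mean sums of squares for a balanced split-plot design.

    ``block``: probe sets (exons) x samples, log2 scale.  Valid only when
    every patient contributes one sample per group (balanced G x P).
    Returns SS on the raw (probe-level) scale, matching ``fit_gene_mlm``.
    """
    design = design.set_index("sample").loc[list(block.columns)].reset_index()
    y = block.to_numpy(dtype=float)
    k, n_s = y.shape
    g = design[group_col].to_numpy()
    p = design["patient"].to_numpy()

    # --- whole-plot stratum on per-sample means
    m = y.mean(axis=0)
    grand = m.mean()
    g_mean = {lv: m[g == lv].mean() for lv in np.unique(g)}
    p_mean = {lv: m[p == lv].mean() for lv in np.unique(p)}
    ss_G = k * sum((g_mean[gi] - grand) ** 2 for gi in g)
    ss_P = k * sum((p_mean[pi] - grand) ** 2 for pi in p)
    sse_wp = k * sum(
        (m[s] - g_mean[g[s]] - p_mean[p[s]] + grand) ** 2 for s in range(n_s)
    )

    # --- subplot stratum
    e_mean = y.mean(axis=1)                      # per-exon mean
    ybar = y.mean()
    eg_mean = {lv: y[:, g == lv].mean(axis=1) for lv in np.unique(g)}
    gbar = {lv: y[:, g == lv].mean() for lv in np.unique(g)}
    n_g = {lv: int((g == lv).sum()) for lv in np.unique(g)}
    ss_E = n_s * ((e_mean - ybar) ** 2).sum()
    ss_EG = sum(
        n_g[lv] * ((eg_mean[lv] - e_mean - gbar[lv] + ybar) ** 2).sum()
        for lv in np.unique(g)
    )
    resid = y - m[None, :]
    for s in range(n_s):
        resid[:, s] -= eg_mean[g[s]] - gbar[g[s]]
    sse = (resid**2).sum()
    return {"G": ss_G, "P": ss_P, "E": ss_E, "E:G": ss_EG,
            "S(G*P)": sse_wp, "residual": sse}


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def lstsq_splitplot_ss(block: pd.DataFrame, design: pd.DataFrame,
                       group_col: str = "pathology") -> dict:
    """Split-plot SS via explicit dummy-matrix least squares (any design).

    Whole-plot terms are R(term | other terms) on the per-sample means,
    subplot terms are sequential increments over the sample factor; on a
    balanced design this coincides with :func:`balanced_splitplot_ss`.
    """
    design = design.set_index("sample").loc[list(block.columns)].reset_index()
    y2d = block.to_numpy(dtype=float)
    k, n_s = y2d.shape
    d = lambda v: pd.get_dummies(pd.Series(v).astype(str)).to_numpy(float)

    m = y2d.mean(axis=0)
    ones = np.ones((n_s, 1))
    G, P = d(design[group_col]), d(design["patient"])
    rss_full = _rss(m, np.hstack([ones, G, P]))
    ss_G = k * (_rss(m, np.hstack([ones, P])) - rss_full)
    ss_P = k * (_rss(m, np.hstack([ones, G])) - rss_full)
    sse_wp = k * rss_full

    y = y2d.ravel(order="C")
    exon = np.repeat(np.arange(k), n_s)
    samp = np.tile(np.arange(n_s), k)
    grp = design[group_col].to_numpy()[samp]
    S, E = d(samp), d(exon)
    EG = d([f"{e}|{gg}" for e, gg in zip(exon, grp)])
    rss_s = _rss(y, S)
    rss_se = _rss(y, np.hstack([S, E]))
    rss_seg = _rss(y, np.hstack([S, E, EG]))
    return {"G": ss_G, "P": ss_P, "E": rss_s - rss_se, "E:G": rss_se - rss_seg,
            "S(G*P)": sse_wp, "residual": rss_seg}
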