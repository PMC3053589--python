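"""Detection-above-background (DABG) calls and the background filter.

A background model is fitted per sample to the labelled genomic and
anti-genomic background probes, stratified by probe GC content.  Each
perfect-match probe receives an upper-tail empirical p-value against the
background distribution of its GC bin; probe-level p-values are combined
per probe set (Stouffer by default).  A probe set is *present* in a
pathology group when p <= alpha in at least 75% of that group's samples;
probe sets absent in every group are filtered out, and genes left with
fewer than five present probe sets are removed entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, floor
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BackgroundModel",
    "DabgCalls",
    "FilterReport",
    "fit_background_model",
    "dabg_pvalues",
    "present_calls",
    "apply_background_filter",
]


@dataclass
class BackgroundModel:
    """Per-sample empirical background distributions per GC bin.

    ``distributions[sample][gc]`` is the sorted array of background-probe
    intensities in that GC bin; ``bin_of`` maps each raw GC count to the
    bin actually used after sparse-bin merging.
    """

    distributions: dict[str, dict[int, np.ndarray]]
    bin_of: dict[int, int]

    def lookup(self, sample: str, gc: int) -> np.ndarray:
        bins = self.distributions[sample]
        if gc in self.bin_of:
            return bins[self.bin_of[gc]]
        # unknown GC -> nearest fitted bin
        nearest = min(bins, key=lambda b: abs(b - gc))
        return bins[nearest]


@dataclass
class DabgCalls:
    p: pd.DataFrame                # probe_set x sample detection p-values
    present: pd.DataFrame = field(default_factory=pd.DataFrame)
    # probe_set x group booleans


@dataclass
class FilterReport:
    removed_probe_sets: list[str]
    removed_genes: list[str]
    retained_probe_sets: list[str]
    retained_genes: list[str]

    @property
    def n_removed_probe_sets(self) -> int:
        return len(self.removed_probe_sets)

    @property
    def n_removed_genes(self) -> int:
        return len(self.removed_genes)

    def to_dict(self) -> dict:
        return {
            "n_removed_probe_sets": self.n_removed_probe_sets,
            "n_removed_genes": self.n_removed_genes,
            "removed_probe_sets": self.removed_probe_sets,
            "removed_genes": self.removed_genes,
            "n_retained_probe_sets": len(self.retained_probe_sets),
            "n_retained_genes": len(self.retained_genes),
        }


def fit_background_model(
    raw: pd.DataFrame,
    background_probe_ids: list[str],
    probe_gc: Mapping[str, int],
    *,
    min_bin_size: int = 20,
) -> BackgroundModel:
    """Fit per-sample x GC-bin empirical background distributions.

    Bins with fewer than ``min_bin_size`` background probes are merged with
    the nearest populated bin (towards the closer neighbour in GC).
    """
    bg_ids = [p for p in background_probe_ids if p in raw.index]
    if not bg_ids:
        raise ValueError("no background probes found in the intensity matrix")
    gcs = np.array([probe_gc[p] for p in bg_ids])
    counts = {int(g): int((gcs == g).sum()) for g in np.unique(gcs)}

    # merge sparse bins into their nearest neighbour until all used bins
    # meet the minimum size
    merged_into: dict[int, int] = {g: g for g in counts}

    def resolve(g: int) -> int:
        while merged_into[g] != g:
            g = merged_into[g]
        return g

    changed = True
    while changed:
        changed = False
        sizes: dict[int, int] = {}
        for g, n in counts.items():
            sizes[resolve(g)] = sizes.get(resolve(g), 0) + n
        small = [g for g, n in sorted(sizes.items()) if n < min_bin_size]
        others = [g for g in sizes if sizes[g] >= min_bin_size]
        if small and others:
            g = small[0]
            target = min(others, key=lambda o: abs(o - g))
            warnings.warn(
                f"GC bin {g} has {sizes[g]} background probes; merged into bin {target}",
                stacklevel=2,
            )
            merged_into[g] = target
            changed = True

    bin_of = {g: resolve(g) for g in counts}
    bg_values = raw.loc[bg_ids]
    distributions: dict[str, dict[int, np.ndarray]] = {}
    used_bins = sorted(set(bin_of.values()))
    member = {b: np.array([bin_of[int(g)] == b for g in gcs]) for b in used_bins}
    for sample in raw.columns:
        col = bg_values[sample].to_numpy(dtype=float)
        distributions[sample] = {b: np.sort(col[member[b]]) for b in used_bins}
    # GC counts never observed among background probes resolve at lookup time
    return BackgroundModel(distributions=distributions, bin_of=bin_of)


def _probe_pvalues(
    intensities: pd.DataFrame,
    model: BackgroundModel,
    probe_gc: Mapping[str, int],
) -> pd.DataFrame:
    """Upper-tail empirical rank p per probe: (#background >= x + 1)/(n + 1)."""
    out = np.empty(intensities.shape)
    gcs = [probe_gc.get(p, 12) for p in intensities.index]
    for j, sample in enumerate(intensities.columns):
        col = intensities[sample].to_numpy(dtype=float)
        for i, gc in enumerate(gcs):
            bg = model.lookup(sample, gc)
            n = len(bg)
            n_ge = n - np.searchsorted(bg, col[i], side="left")
            out[i, j] = (n_ge + 1) / (n + 1)
    return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)


def dabg_pvalues(
    raw: pd.DataFrame,
    model: BackgroundModel,
    chipdef,
    *,
    method: str = "stouffer",
) -> DabgCalls:
    """Per-probe-set x sample detection p-values.

    Probe-level empirical p-values are combined per probe set with
    Stouffer's method on the normal quantiles (default) or Fisher's method.
    """
    if method not in ("stouffer", "fisher"):
        raise ValueError(f"unknown combination method {method!r}")
    probe_gc = chipdef.probe_gc()
    pm_ids = [p for ps in chipdef.probe_sets.values() for p in ps.probe_ids]
    pm_ids = [p for p in pm_ids if p in raw.index]
    probe_p = _probe_pvalues(raw.loc[pm_ids], model, probe_gc)

    rows = []
    ids = []
    eps = 1e-12
    for psid in sorted(chipdef.probe_sets):
        ps = chipdef.probe_sets[psid]
        members = [p for p in ps.probe_ids if p in probe_p.index]
        if not members:
            continue
        block = probe_p.loc[members].to_numpy()
        block = np.clip(block, eps, 1 - eps)
        if method == "stouffer":
            z = stats.norm.isf(block)
            combined = stats.norm.sf(z.sum(axis=0) / np.sqrt(len(members)))
        else:
            chi2 = -2.0 * np.log(block).sum(axis=0)
            combined = stats.chi2.sf(chi2, df=2 * len(members))
        ids.append(psid)
        rows.append(np.clip(combined, eps, 1.0))
    p = pd.DataFrame(rows, index=pd.Index(ids, name="probe_set"), columns=raw.columns)
    return DabgCalls(p=p)


def present_calls(
    p: pd.DataFrame,
    design: pd.DataFrame,
    *,
    alpha: float = 0.01,
    frac: float = 0.75,
    group_col: str = "pathology",
    rounding: str = "ceil",
) -> pd.DataFrame:
    """Per-group present/absent calls.

    A probe set is present in a group when p <= ``alpha`` in at least
    ``frac`` of the group's samples; the required count rounds up by
    default (``rounding='floor'`` rounds down).
    """
    if rounding not in ("ceil", "floor"):
        raise ValueError(f"unknown rounding {rounding!r}")
    round_fn = ceil if rounding == "ceil" else floor
    groups = design.groupby(group_col)["sample"].agg(list)
    out = {}
    for group, samples in groups.items():
        samples = [s for s in samples if s in p.columns]
        if not samples:
            warnings.warn(f"group {group} has no samples; treated as absent", stacklevel=2)
            out[group] = pd.Series(False, index=p.index)
            continue
        need = max(round_fn(frac * len(samples)), 1)
        hits = (p[samples] <= alpha).sum(axis=1)
        out[group] = hits >= need
    return pd.DataFrame(out)


def apply_background_filter(
    present: pd.DataFrame,
    probeset_to_gene: Mapping[str, str],
    *,
    min_present_probe_sets: int = 5,
) -> FilterReport:
    """Apply the background filter.

    A probe set is removed iff it is absent in every group; a gene is
    removed entirely when fewer than ``min_present_probe_sets`` of its
    probe sets are present in at least one group.
    """
    absent_everywhere = ~present.any(axis=1)
    removed_ps = sorted(present.index[absent_everywhere])

    genes: dict[str, list[str]] = {}
    for ps in present.index:
        genes.setdefault(probeset_to_gene.get(ps, "?"), []).append(ps)
    removed_genes = []
    retained_genes = []
    retained_ps: list[str] = []
    for gene, members in sorted(genes.items()):
        n_present = int(present.loc[members].any(axis=1).sum())
        if n_present < min_present_probe_sets:
            removed_genes.append(gene)
        else:
            retained_genes.append(gene)
            retained_ps.extend(ps for ps in members if present.loc[ps].any())
    return FilterReport(
        removed_probe_sets=removed_ps,
        removed_genes=removed_genes,
        retained_probe_sets=sorted(retained_ps),
        retained_genes=retained_genes,
    )
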