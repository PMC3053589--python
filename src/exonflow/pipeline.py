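"""End-to-end workflow orchestration.

Runs the enhanced differential-splicing workflow over a dataset (simulated
or supplied): chip re-definition from transcript annotation, probe-level
preprocessing, detection-above-background filtering, mixed-model splicing
ANOVA, candidate selection, and — when Ct tables are present — the qRT-PCR
validation calculus.  Every stage writes plain-text outputs into the run
directory and is recorded in a JSON manifest; reruns with the same
configuration are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import SplicingAnova
from .candidates import (
    delta_logp_diagnostic,
    read_known_alt,
    select_candidates,
)
from .chipdef import build_chipdef, read_probe_library, write_chipdef
from .dabg import (
    apply_background_filter,
    dabg_pvalues,
    fit_background_model,
    present_calls,
)
from .preprocess import (
    background_adjust,
    quantile_normalize,
    summarize_gene_level,
    summarize_probesets,
)
from .qpcr import compute_event_stats, normalize_ct, qrt_outcome, rtpcr_outcome
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("exonflow")

STAGES = (
    "simulate",
    "build_chipdef",
    "preprocess",
    "dabg",
    "splice_anova",
    "candidates",
    "validate_qpcr",
)


@dataclass
class RunConfig:
    """All inputs, outputs and thresholds of one workflow run.

    Threshold defaults are the workflow's canonical operating point: DABG
    alpha 0.01 with a 75% per-group present rule, at least five present
    probe sets per gene, FDR 0.05 on the splicing interaction, sub-list
    size 100, splicing-index cut 1.4 for catalogued events, qRT-PCR alpha
    0.05 and SI cut 2.0, and a 0.5 log2 threshold for subtype-specific
    splicing differences.
    """

    out_dir: str = "runs/run1"
    simulate: bool = True
    seed: int = 0
    mode: str = "pathology"
    # input paths (used when simulate is false)
    gtf: str | None = None
    probes: str | None = None
    repeats: str | None = None
    intensities: str | None = None
    design: str | None = None
    known_alt: str | None = None
    ct_table: str | None = None
    rtpcr_table: str | None = None
    # thresholds (workflow defaults)
    dabg_alpha: float = 0.01
    present_fraction: float = 0.75
    min_probe_sets: int = 5
    fdr: float = 0.05
    sublist_top: int = 100
    si_threshold: float = 1.4
    qpcr_alpha: float = 0.05
    qpcr_si_threshold: float = 2.0
    subtype_delta_log2_si: float = 0.5
    background_filter: bool = True
    simulation: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def _require(path: str | None, name: str) -> Path:
    if path is None or not Path(path).exists():
        raise PipelineError(f"required input '{name}' not found: {path}")
    return Path(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in workflow order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }

    def record(stage: str, **counts) -> None:
        logger.info("stage %s done: %s", stage, counts)
        manifest["stages"].append({"stage": stage, **counts})

    # --- stage 1: simulate or ingest
    if config.simulate:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
        paths = simulate_dataset(sim_cfg, out / "data")
        config.gtf = str(paths["gtf"])
        config.probes = str(paths["probes"])
        config.intensities = str(paths["intensities"])
        config.design = str(paths["design"])
        config.known_alt = str(paths["known_alt"])
        if "ct" in paths:
            config.ct_table = str(paths["ct"])
            config.rtpcr_table = str(paths["rtpcr"])
        record("simulate", n_files=len(paths))
    else:
        record("simulate", skipped=True)

    # --- stage 2: chip re-definition
    try:
        chip = build_chipdef(
            _require(config.gtf, "gtf"),
            _require(config.probes, "probes"),
            config.repeats if config.repeats and Path(config.repeats).exists() else None,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage build_chipdef failed: {exc}") from exc
    write_chipdef(chip, out / "chipdef")
    record("build_chipdef", n_probe_sets=len(chip.probe_sets), n_clusters=len(chip.clusters))

    # --- stage 3: preprocessing
    raw = pd.read_csv(_require(config.intensities, "intensities"), sep="\t", index_col=0)
    design = pd.read_csv(_require(config.design, "design"), sep="\t")
    probes_lib = read_probe_library(config.probes)
    bg_ids = list(probes_lib.loc[probes_lib.get("probe_type", "") == "background", "probe_id"])
    probe_gc = {
        row.probe_id: row.sequence.upper().count("G") + row.sequence.upper().count("C")
        for row in probes_lib.itertuples(index=False)
    }
    try:
        norm = quantile_normalize(raw)
        adjusted = background_adjust(norm, probe_gc, bg_ids) if bg_ids else norm
        expr_ps = summarize_probesets(adjusted, chip)
        expr_gene = summarize_gene_level(expr_ps, chip)
    except Exception as exc:
        raise PipelineError(f"stage preprocess failed: {exc}") from exc
    expr_ps.to_csv(out / "expr_probesets.tsv", sep="\t", float_format="%.6f")
    expr_gene.to_csv(out / "expr_genes.tsv", sep="\t", float_format="%.6f")
    record("preprocess", n_probe_sets=len(expr_ps), n_genes=len(expr_gene))

    # --- stage 4: DABG + background filter
    ps_to_gene = chip.probeset_to_cluster()
    if config.background_filter and bg_ids:
        try:
            model = fit_background_model(norm, bg_ids, probe_gc)
            calls = dabg_pvalues(norm, model, chip)
            present = present_calls(
                calls.p, design, alpha=config.dabg_alpha, frac=config.present_fraction
            )
            report = apply_background_filter(
                present, ps_to_gene, min_present_probe_sets=config.min_probe_sets
            )
        except Exception as exc:
            raise PipelineError(f"stage dabg failed: {exc}") from exc
        calls.p.to_csv(out / "dabg_pvalues.tsv", sep="\t", float_format="%.6g")
        present.to_csv(out / "present_calls.tsv", sep="\t")
        (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        keep_ps = [ps for ps in expr_ps.index if ps in set(report.retained_probe_sets)]
        record(
            "dabg",
            n_removed_probe_sets=report.n_removed_probe_sets,
            n_removed_genes=report.n_removed_genes,
            n_retained_probe_sets=len(keep_ps),
        )
    else:
        keep_ps = list(expr_ps.index)
        record("dabg", skipped=True)

    expr_ps_f = expr_ps.loc[keep_ps]
    expr_gene_f = summarize_gene_level(expr_ps_f, chip)

    # --- stage 5: splicing ANOVA
    try:
        model = SplicingAnova(
            expr_ps_f, expr_gene_f, design, ps_to_gene,
            mode=config.mode, min_probe_sets=config.min_probe_sets,
        )
        model.subtype_delta_threshold = config.subtype_delta_log2_si
        results = model.fit(fdr=config.fdr)
    except Exception as exc:
        raise PipelineError(f"stage splice_anova failed: {exc}") from exc
    results.write(out / "splice_anova")
    record(
        "splice_anova",
        n_genes=len(results.gene_table),
        n_significant=int((results.gene_table["q_AS"] <= config.fdr).sum()),
    )

    # --- stage 6: candidate selection
    try:
        known_alt = (
            read_known_alt(config.known_alt)
            if config.known_alt and Path(config.known_alt).exists()
            else pd.DataFrame(
                columns=["bin", "chrom", "chromStart", "chromEnd", "name", "score", "strand"]
            )
        )
        coords = pd.read_csv(out / "chipdef" / "annotation.csv")
        lists = select_candidates(
            results, known_alt, coords,
            fdr=config.fdr, top=config.sublist_top, si_thresh=config.si_threshold,
        )
    except Exception as exc:
        raise PipelineError(f"stage candidates failed: {exc}") from exc
    (out / "candidates.json").write_text(
        json.dumps(
            {
                "primary": lists.primary,
                "p_threshold": lists.p_threshold,
                "A": lists.A,
                "B": lists.B,
                "C": lists.C,
                "final": lists.final,
                "venn": lists.venn_counts(),
            },
            indent=2,
        )
    )
    lists.membership_table().to_csv(out / "final_list.tsv", sep="\t", index=False)
    record("candidates", n_primary=len(lists.primary), n_final=len(lists.final))

    # --- stage 7: qRT-PCR validation
    if config.ct_table and Path(config.ct_table).exists():
        try:
            val_table = _validate_stage(config, design, results, ps_to_gene, chip)
        except Exception as exc:
            raise PipelineError(f"stage validate_qpcr failed: {exc}") from exc
        val_table.to_csv(out / "validation.tsv", sep="\t", index=False)
        record(
            "validate_qpcr",
            n_events=len(val_table),
            n_validated=int((val_table["status"] == "validated").sum()),
        )
    else:
        record("validate_qpcr", skipped=True)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _validate_stage(config: RunConfig, design, results, ps_to_gene, chip) -> pd.DataFrame:
    """qRT-PCR validation of the simulated/provided splicing events."""
    ct = pd.read_csv(config.ct_table, sep="\t")
    dct = normalize_ct(ct)
    rt = (
        pd.read_csv(config.rtpcr_table, sep="\t")
        if config.rtpcr_table and Path(config.rtpcr_table).exists()
        else pd.DataFrame(columns=["gene", "rt_pcr"])
    )
    rt_map = dict(zip(rt["gene"], rt["rt_pcr"]))

    # locus -> transcript cluster, to read the exon-array hypothesis
    locus_to_cluster = {}
    for cl in chip.clusters.values():
        for locus in cl.gene_locus_ids:
            locus_to_cluster[locus] = cl.cluster_id

    events = sorted(
        {a.rsplit(":", 1)[0] for a in dct.index if a.rsplit(":", 1)[-1] in ("gene", "inclusion")}
    )
    rows = []
    subtypes = sorted(design.loc[design["pathology"] == "tumour", "subtype"].unique()) \
        if "subtype" in design.columns else []
    for gene in events:
        gene_assay, var_assay = f"{gene}:gene", f"{gene}:inclusion"
        if gene_assay not in dct.index or var_assay not in dct.index:
            continue
        # exon-array hypothesis: direction of the gene's most extreme SI
        cluster = locus_to_cluster.get(gene)
        direction = 1
        if cluster is not None and len(results.probeset_table):
            sub = results.probeset_table[results.probeset_table["gene"] == cluster]
            if len(sub):
                ext = sub.loc[sub["log2_si"].abs().idxmax(), "log2_si"]
                direction = 1 if ext >= 0 else -1
        row = {"gene": gene, "hypothesis": "cassette exon", "rt_pcr": rt_map.get(gene, "N/A")}
        qrt = {}
        for st in subtypes or ["all"]:
            sub_design = (
                design[design["patient"].isin(design.loc[design["subtype"] == st, "patient"])]
                if st != "all" else design
            )
            stats_st = compute_event_stats(dct, sub_design, gene_assay, var_assay, gene=gene)
            outcome = qrt_outcome(
                stats_st, direction,
                alpha=config.qpcr_alpha, si_thresh=config.qpcr_si_threshold,
            )
            qrt[st] = outcome
            row[f"qrt_{st}"] = outcome
            row[f"median_si_{st}"] = stats_st.median_si
        from .qpcr import ValidationEvent, validation_status

        ev = ValidationEvent(gene=gene, hypothesis=row["hypothesis"],
                             rt_pcr=row["rt_pcr"], qrt=qrt)
        row["status"] = validation_status(ev)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_workflows(config: RunConfig) -> dict:
    """Contrast the standard (no background filter) and enhanced runs.

    Both arms share the simulated data and chip definition; the report
    counts genes removed and gained by the filter, the overlap of the two
    significant-gene lists, and — when enough genes changed — the
    delta-log-p skewness diagnostic.
    """
    import copy

    base = Path(config.out_dir)
    cfg_enh = copy.deepcopy(config)
    cfg_enh.out_dir = str(base / "enhanced")
    # honour the configured flag: disabling it compares two unfiltered runs
    cfg_enh.background_filter = config.background_filter
    cfg_std = copy.deepcopy(config)
    cfg_std.out_dir = str(base / "standard")
    cfg_std.background_filter = False
    run_pipeline(cfg_enh)
    # reuse the simulated data so both arms see identical inputs
    if config.simulate:
        cfg_std.simulate = False
        for attr in ("gtf", "probes", "intensities", "design", "known_alt",
                     "ct_table", "rtpcr_table"):
            setattr(cfg_std, attr, getattr(cfg_enh, attr))
    run_pipeline(cfg_std)

    enh = json.loads((base / "enhanced" / "candidates.json").read_text())
    std = json.loads((base / "standard" / "candidates.json").read_text())
    set_enh, set_std = set(enh["primary"]), set(std["primary"])
    p_enh = pd.read_csv(base / "enhanced/splice_anova/genes.tsv", sep="\t", index_col=0)["p_AS"]
    p_std = pd.read_csv(base / "standard/splice_anova/genes.tsv", sep="\t", index_col=0)["p_AS"]
    changed = sorted((set_enh ^ set_std) & set(p_enh.index) & set(p_std.index))
    report = {
        "n_enhanced": len(set_enh),
        "n_standard": len(set_std),
        "n_overlap": len(set_enh & set_std),
        "n_removed_by_filter": len(set_std - set_enh),
        "n_gained_with_filter": len(set_enh - set_std),
    }
    if len(changed) >= 8:
        skew, pval = delta_logp_diagnostic(p_std.loc[changed], p_enh.loc[changed])
        report["delta_logp_skewness"] = skew
        report["delta_logp_skewtest_p"] = pval
    (base / "compare_report.json").write_text(json.dumps(report, indent=2))
    return report
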