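"""Synthetic exon-array experiment generator.

Emulates a paired tumour/NAT exon-array study of non-small-cell lung cancer:
a toy transcript annotation (genes with cassette-exon transcript variants),
a 25-mer probe library with controlled GC content, a probe x sample
intensity matrix with planted gene-level fold-changes, tumour-specific exon
inclusion switches, background-level (absent) exons, cross-hybridizing
probes and GC-dependent background noise, plus qRT-PCR Ct tables for the
validation calculus.  Every planted effect is recorded in a ground-truth
sidecar so each downstream stage can be scored against what was simulated.

All randomness flows from the seed in :class:`SimulationConfig`; identical
configurations produce byte-identical output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Annotation",
    "generate_annotation",
    "generate_design",
    "generate_probe_library",
    "simulate_intensities",
    "simulate_qpcr",
    "simulate_gene_block",
    "write_known_alt",
    "simulate_dataset",
]

_BASES_AT = np.array(list("AT"))
_BASES_GC = np.array(list("GC"))

PROBE_LENGTH = 25


class SimulationError(ValueError):
    """Invalid simulation configuration or inconsistent inputs."""


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise SimulationError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic paired tumour/NAT exon-array experiment.

    Defaults describe a small but fully featured study: 30 genes of 6-10
    exons, 6 patients (matched tumour and adjacent-normal sample each, half
    adenocarcinoma, half squamous), 20% of genes carrying a one-exon
    cassette switch of one log2 unit in tumour, 20% carrying a gene-level
    fold-change, 10% of exons expressed in neither group, and log2-normal
    probe noise of 0.25 — the residual scale typical of summarised exon
    arrays.
    """

    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (6, 10)
    n_patients: int = 6
    subtype_split: float = 0.5
    frac_spliced_genes: float = 0.2
    splicing_log2_effect: float = 1.0
    frac_de_genes: float = 0.2
    de_log2_effect: float = 1.0
    frac_absent_exons: float = 0.1
    frac_crosshyb_probes: float = 0.02
    probe_noise_sd: float = 0.25
    patient_sd: float = 0.5
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    crosshyb_log2_offset: float = 2.0
    probes_per_exon: int = 4
    exon_width: int = 120
    intron_width: int = 100
    gc_range: tuple[int, int] = (5, 20)
    n_background_probes: int = 600
    background_mean_by_gc: dict[int, float] | None = None
    qpcr_noise_sd: float = 0.15
    qpcr_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "subtype_split", "frac_spliced_genes", "frac_de_genes",
            "frac_absent_exons", "frac_crosshyb_probes",
        ):
            _check_fraction(name, getattr(self, name))
        if self.n_patients < 2:
            raise SimulationError("n_patients must be >= 2")
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise SimulationError(f"invalid exons_per_gene range {self.exons_per_gene}")
        for name in ("splicing_log2_effect", "de_log2_effect"):
            if not np.isfinite(getattr(self, name)):
                raise SimulationError(f"{name} must be finite")
        if self.probe_noise_sd < 0 or self.patient_sd < 0:
            raise SimulationError("noise standard deviations must be >= 0")
        if self.background_mean_by_gc is None:
            # background brightens with probe GC content, ~4-6 log2 units
            self.background_mean_by_gc = {
                gc: 4.0 + 0.08 * gc for gc in range(PROBE_LENGTH + 1)
            }

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent random stream derived from the config seed."""
        key = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Record of all planted effects, keyed by generated identifiers."""

    spliced: dict[str, dict] = field(default_factory=dict)
    # gene_id -> {"exon_id": ..., "log2_si": ...}
    de_genes: dict[str, float] = field(default_factory=dict)  # gene_id -> log2 FC
    absent_exons: dict[str, list[str]] = field(default_factory=dict)
    # exon_id -> groups in which the exon is background-level
    crosshyb_probes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class Annotation:
    """Toy transcript annotation: exon table plus transcript structures."""

    exons: pd.DataFrame
    # columns: gene_id, exon_id, chrom, start, end, strand, exon_index
    transcripts: pd.DataFrame
    # columns: gene_id, transcript_id, exon_id (one row per exon membership)

    def to_gtf(self, path: str | Path) -> None:
        ex = self.exons.set_index("exon_id")
        lines = []
        merged = self.transcripts.merge(
            self.exons, on=["gene_id", "exon_id"]
        ).sort_values(["gene_id", "transcript_id", "start"])
        for row in merged.itertuples(index=False):
            attrs = (
                f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}"; '
                f'exon_id "{row.exon_id}";'
            )
            lines.append(
                f"{row.chrom}\texonflow_sim\texon\t{row.start + 1}\t{row.end}"
                f"\t.\t{row.strand}\t.\t{attrs}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def generate_annotation(config: SimulationConfig) -> tuple[Annotation, GroundTruth]:
    """Generate gene loci with cassette-exon transcript variants.

    Each gene gets an inclusion transcript spanning all its exons; genes
    selected as spliced additionally get a skipping transcript lacking one
    internal cassette exon, which in tumour samples shifts by
    ``splicing_log2_effect`` log2 units.
    """
    rng = config.rng("annotation")
    truth = GroundTruth()
    exon_rows = []
    tx_rows = []
    pos = 1000
    n_spliced = int(round(config.frac_spliced_genes * config.n_genes))
    n_de = int(round(config.frac_de_genes * config.n_genes))
    gene_ids = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    spliced_ids = set(rng.choice(gene_ids, size=n_spliced, replace=False)) if n_spliced else set()
    de_ids = set(rng.choice(gene_ids, size=n_de, replace=False)) if n_de else set()

    lo, hi = config.exons_per_gene
    all_internal_exons: list[str] = []
    for gid in gene_ids:
        n_ex = int(rng.integers(lo, hi + 1))
        if gid in spliced_ids and n_ex < 3:
            n_ex = 3  # a cassette exon needs flanking constitutive exons
        strand = "+" if rng.random() < 0.5 else "-"
        exon_ids = []
        for k in range(n_ex):
            eid = f"{gid}:E{k + 1:03d}"
            exon_rows.append((gid, eid, "chr1", pos, pos + config.exon_width, strand, k))
            exon_ids.append(eid)
            pos += config.exon_width + config.intron_width
            if k < n_ex - 1:
                all_internal_exons.append(eid) if 0 < k else None
        pos += 5 * config.intron_width  # intergenic gap

        tx_inc = f"{gid}.T1"
        for eid in exon_ids:
            tx_rows.append((gid, tx_inc, eid))
        if gid in spliced_ids:
            cass_idx = int(rng.integers(1, n_ex - 1))
            cass = exon_ids[cass_idx]
            tx_skip = f"{gid}.T2"
            for eid in exon_ids:
                if eid != cass:
                    tx_rows.append((gid, tx_skip, eid))
            truth.spliced[gid] = {
                "exon_id": cass,
                "log2_si": float(config.splicing_log2_effect),
            }
        if gid in de_ids:
            truth.de_genes[gid] = float(config.de_log2_effect)

    exons = pd.DataFrame(
        exon_rows,
        columns=["gene_id", "exon_id", "chrom", "start", "end", "strand", "exon_index"],
    )
    transcripts = pd.DataFrame(tx_rows, columns=["gene_id", "transcript_id", "exon_id"])

    # absent exons: internal, constitutive, background-level in both groups
    cassette = {v["exon_id"] for v in truth.spliced.values()}
    candidates = [e for e in all_internal_exons if e not in cassette]
    n_absent = int(round(config.frac_absent_exons * len(exons)))
    n_absent = min(n_absent, len(candidates))
    if n_absent:
        chosen = rng.choice(candidates, size=n_absent, replace=False)
        for eid in chosen:
            truth.absent_exons[str(eid)] = ["tumour", "NAT"]
    return Annotation(exons=exons, transcripts=transcripts), truth


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Paired design: one tumour and one NAT sample per patient.

    The first ``subtype_split`` fraction of patients are adenocarcinoma
    (AdCa), the rest squamous cell carcinoma (SCC).
    """
    rows = []
    n_adca = int(round(config.subtype_split * config.n_patients))
    for i in range(1, config.n_patients + 1):
        patient = f"P{i:02d}"
        subtype = "AdCa" if i <= n_adca else "SCC"
        rows.append((f"{patient}_T", patient, "tumour", subtype))
        rows.append((f"{patient}_N", patient, "NAT", subtype))
    return pd.DataFrame(rows, columns=["sample", "patient", "pathology", "subtype"])


def _random_probe_seq(rng: np.random.Generator, gc_count: int) -> str:
    seq = np.empty(PROBE_LENGTH, dtype="<U1")
    gc_pos = rng.choice(PROBE_LENGTH, size=gc_count, replace=False)
    mask = np.zeros(PROBE_LENGTH, dtype=bool)
    mask[gc_pos] = True
    seq[mask] = rng.choice(_BASES_GC, size=gc_count)
    seq[~mask] = rng.choice(_BASES_AT, size=PROBE_LENGTH - gc_count)
    return "".join(seq)


def generate_probe_library(
    annotation: Annotation,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Generate a 25-mer probe library covering every exon.

    ``probes_per_exon`` probes are placed at distinct offsets within each
    exon; a ``frac_crosshyb_probes`` fraction receive a second genomic hit
    (hit_count = 2), marking them cross-hybridizing.  Labelled background
    probes (genomic/anti-genomic surrogates, chrom ``chrBG``) spanning the
    configured GC range are appended for background-model fitting.
    """
    rng = config.rng("probes")
    rows = []
    gc_lo, gc_hi = config.gc_range
    for ex in annotation.exons.itertuples(index=False):
        width = ex.end - ex.start
        n = config.probes_per_exon
        span = max(width - PROBE_LENGTH, 1)
        offsets = np.unique((np.arange(n) * span // max(n - 1, 1)).astype(int))
        # ensure n distinct offsets even in narrow exons
        while len(offsets) < n:
            offsets = np.append(offsets, offsets[-1] + 1)
        for j, off in enumerate(offsets[:n], 1):
            gc = int(rng.integers(gc_lo, gc_hi + 1))
            rows.append(
                (
                    f"{ex.exon_id}:p{j}",
                    _random_probe_seq(rng, gc),
                    ex.chrom,
                    int(ex.start + off),
                    int(ex.start + off + PROBE_LENGTH),
                    ex.strand,
                    1,
                    "pm",
                    ex.exon_id,
                    ex.gene_id,
                )
            )
    probes = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "sequence", "chrom", "start", "end", "strand",
            "hit_count", "probe_type", "exon_id", "gene_id",
        ],
    )
    n_xh = int(round(config.frac_crosshyb_probes * len(probes)))
    if n_xh:
        xh_idx = rng.choice(len(probes), size=n_xh, replace=False)
        probes.loc[probes.index[xh_idx], "hit_count"] = 2
        if truth is not None:
            truth.crosshyb_probes = sorted(probes.loc[probes.index[xh_idx], "probe_id"])

    # background probes: one batch per GC bin so every bin is populated
    bg_rows = []
    n_bins = gc_hi - gc_lo + 1
    per_bin = max(config.n_background_probes // n_bins, 1)
    k = 0
    for gc in range(gc_lo, gc_hi + 1):
        for _ in range(per_bin):
            k += 1
            bg_rows.append(
                (
                    f"BG:{k:05d}",
                    _random_probe_seq(rng, gc),
                    "chrBG", (k - 1) * PROBE_LENGTH, k * PROBE_LENGTH, "+",
                    0, "background", "", "",
                )
            )
    bg = pd.DataFrame(bg_rows, columns=probes.columns)
    return pd.concat([probes, bg], ignore_index=True)


def _probe_gc(seq: str) -> int:
    s = seq.upper()
    return s.count("G") + s.count("C")


def simulate_intensities(
    probes: pd.DataFrame,
    design: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate the probe x sample intensity matrix (linear scale).

    On the log2 scale each perfect-match probe is baseline + patient effect
    + group effect (DE genes, tumour only) + exon-inclusion shift (cassette
    exons of spliced genes, tumour only) + cross-hybridization offset +
    N(0, probe_noise_sd) noise.  Probes of absent exons and the labelled
    background probes instead draw from the GC-dependent background
    distribution.  The returned matrix is strictly positive.
    """
    missing = {"sample", "patient", "pathology"} - set(design.columns)
    if missing:
        raise SimulationError(f"design table missing columns: {sorted(missing)}")
    rng = config.rng("intensities")
    genes = sorted(g for g in probes["gene_id"].unique() if g)
    baselines = dict(
        zip(genes, config.baseline_mean + config.baseline_sd * rng.standard_normal(len(genes)))
    )
    patients = sorted(design["patient"].unique())
    patient_eff = dict(zip(patients, config.patient_sd * rng.standard_normal(len(patients))))

    samples = design["sample"].tolist()
    pathology = dict(zip(design["sample"], design["pathology"]))
    patient_of = dict(zip(design["sample"], design["patient"]))
    bg_mean = config.background_mean_by_gc
    assert bg_mean is not None

    crosshyb = set(truth.crosshyb_probes)
    spliced_exon = {v["exon_id"]: (g, v["log2_si"]) for g, v in truth.spliced.items()}

    n_probes, n_samples = len(probes), len(samples)
    log2 = np.empty((n_probes, n_samples))
    noise = config.probe_noise_sd * rng.standard_normal((n_probes, n_samples))
    gcs = probes["sequence"].map(_probe_gc).to_numpy()

    for j, s in enumerate(samples):
        tumour = pathology[s] == "tumour"
        group = pathology[s]
        p_eff = patient_eff[patient_of[s]]
        for i, pr in enumerate(probes.itertuples(index=False)):
            if pr.probe_type == "background":
                log2[i, j] = bg_mean[gcs[i]]
                continue
            if pr.exon_id in truth.absent_exons and group in truth.absent_exons[pr.exon_id]:
                log2[i, j] = bg_mean[gcs[i]]
                continue
            v = baselines[pr.gene_id] + p_eff
            if tumour and pr.gene_id in truth.de_genes:
                v += truth.de_genes[pr.gene_id]
            if tumour and pr.exon_id in spliced_exon:
                v += spliced_exon[pr.exon_id][1]
            if pr.probe_id in crosshyb:
                v += config.crosshyb_log2_offset
            log2[i, j] = v
    log2 += noise
    return pd.DataFrame(2.0 ** log2, index=pd.Index(probes["probe_id"], name="probe_id"),
                        columns=samples)


def simulate_gene_block(
    n_exons: int,
    design: pd.DataFrame,
    log2_si: float = 0.0,
    affected_exon: int = 0,
    de_log2_fc: float = 0.0,
    noise_sd: float = 0.25,
    patient_sd: float = 0.5,
    baseline: float = 8.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one gene's probe-set x sample log2 expression block.

    Convenience generator for studying the splicing ANOVA in isolation: the
    planted interaction is a shift of ``log2_si`` on ``affected_exon`` in
    tumour samples only, on top of patient effects and a gene-level
    fold-change.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    patients = sorted(design["patient"].unique())
    p_eff = dict(zip(patients, patient_sd * rng.standard_normal(len(patients))))
    values = np.empty((n_exons, len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        tumour = row.pathology == "tumour"
        base = baseline + p_eff[row.patient] + (de_log2_fc if tumour else 0.0)
        values[:, j] = base
        if tumour:
            values[affected_exon, j] += log2_si
    values += noise_sd * rng.standard_normal(values.shape)
    return pd.DataFrame(
        values,
        index=pd.Index([f"PS{k + 1:03d}" for k in range(n_exons)], name="probe_set"),
        columns=design["sample"].tolist(),
    )


def write_known_alt(annotation: Annotation, truth: GroundTruth, path: str | Path) -> None:
    """Write planted cassette exons as a UCSC knownAlt-schema TSV."""
    ex = annotation.exons.set_index("exon_id")
    rows = []
    for gid, info in sorted(truth.spliced.items()):
        e = ex.loc[info["exon_id"]]
        rows.append((0, e["chrom"], int(e["start"]), int(e["end"]), "cassetteExon", 0, e["strand"]))
    pd.DataFrame(
        rows, columns=["bin", "chrom", "chromStart", "chromEnd", "name", "score", "strand"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qRT-PCR simulation
# ---------------------------------------------------------------------------

_CONTROL_ASSAYS = {"ESD": 20.0, "POLR2A": 21.0}
_BASE_CT = 24.0


def simulate_qpcr(
    truth: GroundTruth,
    design: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate qRT-PCR Ct tables and endpoint RT-PCR outcomes per event.

    One event per planted spliced gene: a gene-level assay, a
    variant-inclusion assay carrying the planted inclusion shift in tumour,
    and the two endogenous control assays.  Ct decreases by one cycle per
    two-fold expression increase.  The RT-PCR outcome counts patients whose
    noisy per-patient inclusion shift has the planted direction.
    """
    if not truth.spliced:
        raise SimulationError("ground truth contains no splicing event")
    rng = config.rng("qpcr")
    rows = []
    rt_rows = []
    patients = sorted(design["patient"].unique())
    pathology = dict(zip(design["sample"], design["pathology"]))
    de = truth.de_genes
    for gid, info in sorted(truth.spliced.items()):
        si = info["log2_si"]
        per_patient_dir = []
        for s in design["sample"]:
            tumour = pathology[s] == "tumour"
            log2_gene = (de.get(gid, 0.0) if tumour else 0.0)
            log2_var = log2_gene + (si if tumour else 0.0)
            for assay, expr in (
                (f"{gid}:gene", log2_gene),
                (f"{gid}:inclusion", log2_var),
            ):
                atype = "gene" if assay.endswith(":gene") else "variant_inclusion"
                for rep in range(1, config.qpcr_replicates + 1):
                    ct = _BASE_CT - expr + config.qpcr_noise_sd * rng.standard_normal()
                    rows.append((assay, atype, gid, s, rep, round(float(ct), 4)))
            for ctrl, base in _CONTROL_ASSAYS.items():
                for rep in range(1, config.qpcr_replicates + 1):
                    ct = base + config.qpcr_noise_sd * rng.standard_normal()
                    rows.append((f"CTRL:{ctrl}", "control", ctrl, s, rep, round(float(ct), 4)))
        # endpoint RT-PCR: per patient, does the noisy inclusion shift agree?
        for p in patients:
            observed = si + 2 * config.qpcr_noise_sd * rng.standard_normal()
            per_patient_dir.append(np.sign(observed) == np.sign(si) and observed != 0)
        k = int(sum(per_patient_dir))
        rt_rows.append((gid, f"{k}/{len(patients)}"))
    ct_table = pd.DataFrame(
        rows, columns=["assay_id", "assay_type", "gene", "sample_id", "replicate", "Ct"]
    ).drop_duplicates(subset=["assay_id", "sample_id", "replicate"], keep="first")
    rt_table = pd.DataFrame(rt_rows, columns=["gene", "rt_pcr"])
    return ct_table, rt_table


# ---------------------------------------------------------------------------
# one-call dataset writer
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete synthetic dataset.

    Writes annotation GTF, probe library TSV, design TSV, intensity TSV,
    knownAlt TSV, qPCR Ct/RT-PCR TSVs and the ground-truth JSON sidecar;
    returns the mapping of artefact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth = generate_annotation(config)
    design = generate_design(config)
    probes = generate_probe_library(annotation, config, truth)
    intensities = simulate_intensities(probes, design, truth, config)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "probes": outdir / "probes.tsv",
        "design": outdir / "design.tsv",
        "intensities": outdir / "intensities.tsv",
        "known_alt": outdir / "known_alt.tsv",
        "truth": outdir / "ground_truth.json",
    }
    annotation.to_gtf(paths["gtf"])
    probes.to_csv(paths["probes"], sep="\t", index=False)
    design.to_csv(paths["design"], sep="\t", index=False)
    intensities.to_csv(paths["intensities"], sep="\t", float_format="%.6f")
    write_known_alt(annotation, truth, paths["known_alt"])
    truth.to_json(paths["truth"])
    if truth.spliced:
        ct, rt = simulate_qpcr(truth, design, config)
        paths["ct"] = outdir / "qpcr_ct.tsv"
        paths["rtpcr"] = outdir / "rtpcr.tsv"
        ct.to_csv(paths["ct"], sep="\t", index=False)
        rt.to_csv(paths["rtpcr"], sep="\t", index=False)
    return paths
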