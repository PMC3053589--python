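"""Transcript-driven chip re-definition.

Builds a custom chip definition from transcript annotations: collect the
non-redundant exons of every gene locus, split overlapping exons at every
annotated boundary into disjoint probe selection regions (PSRs), assign
uniquely-mapping probes to the PSR that contains them, drop probes hitting
repeat-masked intervals, and group the resulting probe sets into transcript
clusters (gene loci merged whenever a transcript spans more than one locus).

Coordinates are 0-based half-open throughout; the GTF reader converts from
the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree


class ChipDefError(ValueError):
    """Malformed annotation, probe library, or chip-definition file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Genomic span, 0-based half-open, stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ChipDefError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ChipDefError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ExonRecord:
    """One non-redundant exon of a gene locus with its transcript links."""

    exon_id: str
    interval: GenomicInterval
    gene_id: str
    transcript_ids: frozenset[str]


@dataclass(frozen=True)
class PSR:
    """Probe selection region: a maximal exon sub-interval not split by any
    annotated exon boundary of its locus."""

    psr_id: str
    interval: GenomicInterval
    gene_locus_id: str
    source_exon_ids: frozenset[str]


@dataclass(frozen=True)
class ProbeSet:
    psr_id: str
    probeset_id: str
    probe_ids: tuple[str, ...]


@dataclass(frozen=True)
class TranscriptCluster:
    cluster_id: str
    gene_locus_ids: frozenset[str]
    probe_set_ids: tuple[str, ...]  # genomic order


@dataclass
class ChipDefinition:
    """Probe sets over PSRs, grouped into transcript clusters.

    ``probes`` maps probe_id -> (interval, sequence); sequences are retained
    so downstream background models can stratify by GC content.
    """

    psrs: dict[str, PSR] = field(default_factory=dict)
    probe_sets: dict[str, ProbeSet] = field(default_factory=dict)
    clusters: dict[str, TranscriptCluster] = field(default_factory=dict)
    probes: dict[str, tuple[GenomicInterval, str]] = field(default_factory=dict)

    def probeset_to_cluster(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for cl in self.clusters.values():
            for ps in cl.probe_set_ids:
                out[ps] = cl.cluster_id
        return out

    def probe_to_probeset(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for ps in self.probe_sets.values():
            for p in ps.probe_ids:
                out[p] = ps.probeset_id
        return out

    def probe_gc(self) -> dict[str, int]:
        return {
            pid: seq.upper().count("G") + seq.upper().count("C")
            for pid, (_, seq) in self.probes.items()
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChipDefinition):
            return NotImplemented
        return (
            self.psrs == other.psrs
            and self.probe_sets == other.probe_sets
            and self.clusters == other.clusters
            and self.probes == other.probes
        )


# ---------------------------------------------------------------------------
# annotation input
# ---------------------------------------------------------------------------

def read_gtf_exons(path: str | Path) -> pd.DataFrame:
    """Read exon features from a GTF file via gffutils.

    Returns a DataFrame with columns (chrom, start, end, strand, gene_id,
    transcript_id), coordinates converted to 0-based half-open.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:
        raise ChipDefError(f"cannot parse GTF {path}: {exc}") from exc
    rows = []
    for ex in db.features_of_type("exon"):
        start, end = ex.start - 1, ex.end
        if start >= end:
            raise ChipDefError(
                f"{path}: exon start >= end ({ex.start}, {ex.end}) in "
                f"{ex.attributes.get('gene_id', ['?'])[0]}"
            )
        rows.append(
            (
                ex.seqid,
                start,
                end,
                ex.strand,
                ex.attributes.get("gene_id", [""])[0],
                ex.attributes.get("transcript_id", [""])[0],
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id"]
    )


def read_probe_library(path: str | Path) -> pd.DataFrame:
    """Read a probe library TSV (probe_id, sequence, chrom, start, end,
    strand, hit_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    required = {"probe_id", "sequence", "chrom", "start", "end", "strand", "hit_count"}
    missing = required - set(df.columns)
    if missing:
        raise ChipDefError(f"probe library missing columns: {sorted(missing)}")
    return df


def read_repeats_bed(path: str | Path) -> pd.DataFrame:
    """Read repeat-masked intervals from BED (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
        names=["chrom", "start", "end"],
    )
    return df


# ---------------------------------------------------------------------------
# exon collection and PSR construction
# ---------------------------------------------------------------------------

def collect_exons(exon_table: pd.DataFrame) -> list[ExonRecord]:
    """Collect non-redundant exons per gene locus.

    Exons sharing (chrom, start, end, strand) within a locus are merged into
    one record retaining all transcript links.
    """
    if (exon_table["start"] >= exon_table["end"]).any():
        bad = exon_table[exon_table["start"] >= exon_table["end"]].iloc[0]
        raise ChipDefError(
            f"exon with start >= end in gene {bad['gene_id']}: "
            f"{bad['start']}-{bad['end']}"
        )
    records: list[ExonRecord] = []
    grouped = exon_table.groupby(
        ["gene_id", "chrom", "start", "end", "strand"], sort=True
    )["transcript_id"].agg(frozenset)
    counters: dict[str, int] = {}
    for (gene_id, chrom, start, end, strand), tx_ids in grouped.items():
        n = counters.get(gene_id, 0) + 1
        counters[gene_id] = n
        records.append(
            ExonRecord(
                exon_id=f"{gene_id}:E{n:03d}",
                interval=GenomicInterval(chrom, int(start), int(end), strand),
                gene_id=gene_id,
                transcript_ids=tx_ids,
            )
        )
    return records


def build_psrs(exons: Sequence[ExonRecord]) -> list[PSR]:
    """Split a locus's exons at every annotated boundary into disjoint PSRs.

    The output intervals partition the union of exon bases: every boundary of
    an output interval is a boundary of some input exon, and no two output
    intervals overlap.  Loci and strands are handled independently.
    """
    psrs: list[PSR] = []
    by_locus: dict[tuple[str, str, str], list[ExonRecord]] = {}
    for ex in exons:
        key = (ex.gene_id, ex.interval.chrom, ex.interval.strand)
        by_locus.setdefault(key, []).append(ex)
    for (gene_id, chrom, strand), group in sorted(by_locus.items()):
        bounds = sorted(
            {e.interval.start for e in group} | {e.interval.end for e in group}
        )
        n = 0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            covering = frozenset(
                e.exon_id
                for e in group
                if e.interval.start <= lo and hi <= e.interval.end
            )
            if not covering:
                continue  # gap between exons
            n += 1
            psrs.append(
                PSR(
                    psr_id=f"{gene_id}:PSR{n:03d}" if strand == "+" else "",
                    interval=GenomicInterval(chrom, lo, hi, strand),
                    gene_locus_id=gene_id,
                    source_exon_ids=covering,
                )
            )
        # number minus-strand PSRs too (ids assigned after the loop for both
        # strands of a locus would collide; keep simple sequential ids)
    # assign ids deterministically in genomic order per locus
    out: list[PSR] = []
    counters: dict[str, int] = {}
    for psr in sorted(psrs, key=lambda p: (p.gene_locus_id, p.interval)):
        k = counters.get(psr.gene_locus_id, 0) + 1
        counters[psr.gene_locus_id] = k
        out.append(replace(psr, psr_id=f"{psr.gene_locus_id}:PSR{k:03d}"))
    return out


# ---------------------------------------------------------------------------
# probe mapping
# ---------------------------------------------------------------------------

@dataclass
class ProbeAssignment:
    """Result of mapping a probe library onto PSRs."""

    assigned: dict[str, str]            # probe_id -> psr_id
    excluded: dict[str, str]            # probe_id -> reason
    excluded_psrs: dict[str, str]       # psr_id -> reason (repeat regions)


def map_probes(
    probe_library: pd.DataFrame,
    psrs: Sequence[PSR],
    repeats: pd.DataFrame | None = None,
    *,
    repeat_psr_fraction: float = 0.5,
    straddle_rule: str = "midpoint",
    probe_strand: str = "same",
) -> ProbeAssignment:
    """Assign uniquely-mapping probes to the PSR containing them.

    Probes with more than one genomic hit are excluded ("multi-mapping"), as
    are probes overlapping a repeat interval by >= 1 base ("repeat").  PSRs
    with more than ``repeat_psr_fraction`` of their bases repeat-masked are
    excluded entirely.  A probe fully inside a PSR is assigned to it; a probe
    straddling PSR boundaries is assigned to the PSR containing its midpoint
    when ``straddle_rule == "midpoint"`` and dropped when ``"strict"``.
    ``probe_strand`` declares whether probe hits are recorded on the same or
    the opposite strand as their target PSR.
    """
    if straddle_rule not in ("midpoint", "strict"):
        raise ValueError(f"unknown straddle_rule {straddle_rule!r}")
    if probe_strand not in ("same", "opposite"):
        raise ValueError(f"unknown probe_strand {probe_strand!r}")

    rep_trees: dict[str, IntervalTree] = {}
    if repeats is not None and len(repeats):
        for chrom, sub in repeats.groupby("chrom"):
            rep_trees[chrom] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"])
            )

    def repeat_overlap(chrom: str, start: int, end: int) -> int:
        tree = rep_trees.get(chrom)
        if tree is None:
            return 0
        return sum(
            min(end, iv.end) - max(start, iv.begin) for iv in tree.overlap(start, end)
        )

    excluded_psrs: dict[str, str] = {}
    kept_psrs: list[PSR] = []
    for psr in psrs:
        iv = psr.interval
        frac = repeat_overlap(iv.chrom, iv.start, iv.end) / len(iv)
        if frac > repeat_psr_fraction:
            excluded_psrs[psr.psr_id] = "repeat"
        else:
            kept_psrs.append(psr)

    psr_trees: dict[tuple[str, str], IntervalTree] = {}
    flip = {"+": "-", "-": "+"}
    for psr in kept_psrs:
        iv = psr.interval
        target_strand = iv.strand if probe_strand == "same" else flip[iv.strand]
        key = (iv.chrom, target_strand)
        psr_trees.setdefault(key, IntervalTree())[iv.start:iv.end] = psr

    hit_counts = probe_library.groupby("probe_id")["hit_count"].sum()
    row_counts = probe_library.groupby("probe_id").size()

    assigned: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for row in probe_library.itertuples(index=False):
        pid = row.probe_id
        if pid in assigned or pid in excluded:
            continue
        if max(hit_counts[pid], row_counts[pid]) > 1:
            excluded[pid] = "multi-mapping"
            continue
        start, end = int(row.start), int(row.end)
        if repeat_overlap(row.chrom, start, end) > 0:
            excluded[pid] = "repeat"
            continue
        tree = psr_trees.get((row.chrom, row.strand))
        if tree is None:
            excluded[pid] = "no-psr"
            continue
        containing = [
            iv.data
            for iv in tree.overlap(start, end)
            if iv.begin <= start and end <= iv.end
        ]
        if containing:
            assigned[pid] = containing[0].psr_id
            continue
        if straddle_rule == "midpoint":
            mid = (start + end) // 2
            hits = sorted(tree.overlap(mid, mid + 1), key=lambda iv: iv.begin)
            if hits:
                assigned[pid] = hits[0].data.psr_id
                continue
        excluded[pid] = "no-psr"
    return ProbeAssignment(assigned=assigned, excluded=excluded, excluded_psrs=excluded_psrs)


# ---------------------------------------------------------------------------
# chip assembly
# ---------------------------------------------------------------------------

def assemble_chipdef(
    assignment: ProbeAssignment,
    psrs: Sequence[PSR],
    probe_library: pd.DataFrame,
    locus_transcripts: Mapping[str, Iterable[str]],
) -> ChipDefinition:
    """Assemble probe sets and transcript clusters.

    One probe set is created per PSR covered by at least one assigned probe;
    uncovered PSRs are dropped.  Transcript clusters are the connected
    components of the bipartite locus-transcript graph: a transcript
    annotated across two loci merges them into one cluster.
    """
    psr_by_id = {p.psr_id: p for p in psrs}
    probes_by_psr: dict[str, list[str]] = {}
    for pid, psr_id in assignment.assigned.items():
        probes_by_psr.setdefault(psr_id, []).append(pid)

    chip = ChipDefinition()
    lib = probe_library.drop_duplicates("probe_id").set_index("probe_id")
    for psr_id, probe_ids in sorted(probes_by_psr.items()):
        psr = psr_by_id[psr_id]
        chip.psrs[psr_id] = psr
        probeset_id = psr_id.replace("PSR", "PS")
        chip.probe_sets[probeset_id] = ProbeSet(
            psr_id=psr_id,
            probeset_id=probeset_id,
            probe_ids=tuple(sorted(probe_ids)),
        )
        for pid in probe_ids:
            row = lib.loc[pid]
            chip.probes[pid] = (
                GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), row["strand"]),
                str(row["sequence"]),
            )

    # connected components over loci sharing a transcript
    tx_to_loci: dict[str, set[str]] = {}
    covered_loci = {chip.psrs[ps.psr_id].gene_locus_id for ps in chip.probe_sets.values()}
    for locus, txs in locus_transcripts.items():
        for tx in txs:
            tx_to_loci.setdefault(tx, set()).add(locus)
    parent: dict[str, str] = {loc: loc for loc in covered_loci}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for loci in tx_to_loci.values():
        loci = [l for l in loci if l in parent]
        for a, b in zip(loci, loci[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    comp: dict[str, list[str]] = {}
    for loc in covered_loci:
        comp.setdefault(find(loc), []).append(loc)

    for root, loci in sorted(comp.items()):
        members = [
            ps
            for ps in chip.probe_sets.values()
            if chip.psrs[ps.psr_id].gene_locus_id in loci
        ]
        members.sort(key=lambda ps: chip.psrs[ps.psr_id].interval)
        chip.clusters[f"TC:{root}"] = TranscriptCluster(
            cluster_id=f"TC:{root}",
            gene_locus_ids=frozenset(loci),
            probe_set_ids=tuple(ps.probeset_id for ps in members),
        )
    return chip


def build_chipdef(
    gtf_path: str | Path,
    probe_path: str | Path,
    repeats_path: str | Path | None = None,
    **map_kwargs,
) -> ChipDefinition:
    """End-to-end chip re-definition from annotation + probe library files."""
    exon_table = read_gtf_exons(gtf_path)
    probe_library = read_probe_library(probe_path)
    repeats = read_repeats_bed(repeats_path) if repeats_path else None
    exons = collect_exons(exon_table)
    psrs = build_psrs(exons)
    assignment = map_probes(probe_library, psrs, repeats, **map_kwargs)
    locus_tx = (
        exon_table.groupby("gene_id")["transcript_id"].agg(set).to_dict()
    )
    return assemble_chipdef(assignment, psrs, probe_library, locus_tx)


# ---------------------------------------------------------------------------
# chip definition I/O (PGF-dialect + MPS + annotation CSV)
# ---------------------------------------------------------------------------

def write_chipdef(chip: ChipDefinition, outdir: str | Path) -> None:
    """Write the chip definition as three plain-text files.

    ``probesets.pgf``   one header line per probe set followed by indented
                        probe lines (probe_id, GC count, sequence, genomic
                        hit coordinates);
    ``clusters.mps``    TSV transcript_cluster_id -> space-separated probe
                        set ids;
    ``annotation.csv``  one row per probe set with PSR coordinates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gc = chip.probe_gc()
    with open(outdir / "probesets.pgf", "w") as fh:
        fh.write("#%chip=exonflow-redefined\n")
        for psid in sorted(chip.probe_sets):
            ps = chip.probe_sets[psid]
            fh.write(f"{psid}\tmain\t{ps.psr_id}\n")
            for pid in ps.probe_ids:
                iv, seq = chip.probes[pid]
                fh.write(
                    f"\t{pid}\t{gc[pid]}\t{seq}\t{iv.chrom}\t{iv.start}"
                    f"\t{iv.end}\t{iv.strand}\n"
                )
    with open(outdir / "clusters.mps", "w") as fh:
        fh.write("transcript_cluster_id\tprobeset_ids\tgene_loci\n")
        for cid in sorted(chip.clusters):
            cl = chip.clusters[cid]
            fh.write(
                f"{cid}\t{' '.join(cl.probe_set_ids)}\t"
                f"{' '.join(sorted(cl.gene_locus_ids))}\n"
            )
    rows = []
    for psid in sorted(chip.probe_sets):
        ps = chip.probe_sets[psid]
        psr = chip.psrs[ps.psr_id]
        iv = psr.interval
        rows.append(
            (
                psid, ps.psr_id, iv.chrom, iv.start, iv.end, iv.strand,
                psr.gene_locus_id, len(ps.probe_ids),
                ";".join(sorted(psr.source_exon_ids)),
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "probeset_id", "psr_id", "chrom", "start", "end", "strand",
            "gene_locus", "n_probes", "source_exons",
        ],
    ).to_csv(outdir / "annotation.csv", index=False)


def read_chipdef(outdir: str | Path) -> ChipDefinition:
    """Read a chip definition written by :func:`write_chipdef`."""
    outdir = Path(outdir)
    chip = ChipDefinition()
    ann = pd.read_csv(outdir / "annotation.csv")
    for row in ann.itertuples(index=False):
        chip.psrs[row.psr_id] = PSR(
            psr_id=row.psr_id,
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            gene_locus_id=row.gene_locus,
            source_exon_ids=frozenset(str(row.source_exons).split(";")),
        )
    current: str | None = None
    with open(outdir / "probesets.pgf") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            if not line.startswith("\t"):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ChipDefError(f"probesets.pgf:{lineno}: bad probe set header")
                psid, _, psr_id = parts
                chip.probe_sets[psid] = ProbeSet(psr_id=psr_id, probeset_id=psid, probe_ids=())
                current = psid
            else:
                parts = line.strip().split("\t")
                if len(parts) != 7 or current is None:
                    raise ChipDefError(f"probesets.pgf:{lineno}: bad probe line")
                pid, _, seq, chrom, start, end, strand = parts
                ps = chip.probe_sets[current]
                chip.probe_sets[current] = ProbeSet(
                    psr_id=ps.psr_id,
                    probeset_id=ps.probeset_id,
                    probe_ids=ps.probe_ids + (pid,),
                )
                chip.probes[pid] = (
                    GenomicInterval(chrom, int(start), int(end), strand),
                    seq,
                )
    mps = pd.read_csv(outdir / "clusters.mps", sep="\t")
    for row in mps.itertuples(index=False):
        chip.clusters[row.transcript_cluster_id] = TranscriptCluster(
            cluster_id=row.transcript_cluster_id,
            gene_locus_ids=frozenset(str(row.gene_loci).split()),
            probe_set_ids=tuple(str(row.probeset_ids).split()),
        )
    return chip
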