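"""qRT-PCR / RT-PCR validation calculus.

Relative quantification by the delta-delta-Ct method: technical replicates
are averaged, assays are normalised to the geometric mean of the endogenous
control genes (equivalently, the arithmetic mean of their Ct values), and
per patient

    ddCt = dCt(tumour) - dCt(NAT)
    FC   = 2 ** (-ddCt)
    SI   = 2 ** -(ddCt_variant - ddCt_gene)  =  FC_variant / FC_gene

A splicing event is scored "+" in a subtype when its direction agrees with
the exon-array hypothesis and either the paired t-test on the per-patient
log2 SI is significant (p <= 0.05) or the median SI is high (>= 2.0 or
<= 1/2.0).  An event is validated when at least one subtype scores "+" and
an available endpoint RT-PCR shows the pattern in a strict majority of
patients.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from math import isnan
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_ct",
    "compute_event_stats",
    "EventStats",
    "qrt_outcome",
    "rtpcr_outcome",
    "ValidationEvent",
    "validation_status",
    "load_reference_validation_table",
    "validate_events",
]

DEGENERATE_P = 1e-16  # reported when per-patient SIs have zero variance


def normalize_ct(
    ct_table: pd.DataFrame,
    control_assays: list[str] | None = None,
) -> pd.DataFrame:
    """Control-normalised dCt per assay x sample.

    Technical replicates are averaged arithmetically on the Ct scale; each
    assay's mean Ct is normalised by subtracting the mean control-assay Ct
    of the same sample (the geometric mean of the control quantities on the
    linear scale).  Samples without any control measurement are skipped
    with a warning.
    """
    required = {"assay_id", "assay_type", "sample_id", "Ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    mean_ct = (
        ct_table.groupby(["assay_id", "assay_type", "sample_id"])["Ct"].mean().reset_index()
    )
    if control_assays is None:
        controls = mean_ct[mean_ct["assay_type"] == "control"]
    else:
        controls = mean_ct[mean_ct["assay_id"].isin(control_assays)]
    if controls.empty:
        raise ValueError("no control assays found in the Ct table")
    ref = controls.groupby("sample_id")["Ct"].mean()

    assays = mean_ct[~mean_ct["assay_id"].isin(controls["assay_id"].unique())].copy()
    ok = assays["sample_id"].isin(ref.index)
    dropped = sorted(assays.loc[~ok, "sample_id"].unique())
    if dropped:
        import warnings

        warnings.warn(f"samples without control assay skipped: {dropped}", stacklevel=2)
    assays = assays[ok]
    assays["dCt"] = assays["Ct"] - assays["sample_id"].map(ref).astype(float)
    return assays.pivot_table(index="assay_id", columns="sample_id", values="dCt")


@dataclass
class EventStats:
    """Per-event delta-delta-Ct summary for one subtype (or pooled)."""

    gene: str
    per_patient: pd.DataFrame  # patient, ddct_gene, ddct_variant, fc, si
    median_fc: float
    median_si: float
    t_pvalue: float | None
    degenerate: bool = False  # zero-variance SI; p reported as < DEGENERATE_P

    @property
    def direction(self) -> int:
        """Sign of the median log2 SI (+1 inclusion up in tumour, -1 down)."""
        return int(np.sign(np.log2(self.median_si))) if self.median_si > 0 else 0


def compute_event_stats(
    dct: pd.DataFrame,
    design: pd.DataFrame,
    gene_assay: str,
    variant_assay: str,
    *,
    gene: str | None = None,
) -> EventStats:
    """Per-patient ddCt, FC and SI of a splicing event plus the summary.

    ``design`` must pair tumour and NAT samples by patient; patients with
    either sample missing are dropped.  The significance test is the
    one-sample (paired) t-test of per-patient log2 SI against zero,
    two-sided; with fewer than two complete pairs no p-value is defined.
    """
    pathology = design.set_index("sample")["pathology"]
    patient_of = design.set_index("sample")["patient"]
    rows = []
    for patient, sub in design.groupby("patient"):
        t = sub.loc[sub["pathology"] == "tumour", "sample"]
        n = sub.loc[sub["pathology"] == "NAT", "sample"]
        if len(t) != 1 or len(n) != 1:
            continue
        t, n = t.iloc[0], n.iloc[0]
        try:
            ddct_gene = float(dct.loc[gene_assay, t] - dct.loc[gene_assay, n])
            ddct_var = float(dct.loc[variant_assay, t] - dct.loc[variant_assay, n])
        except KeyError:
            continue
        if isnan(ddct_gene) or isnan(ddct_var):
            continue
        fc = 2.0 ** (-ddct_var)
        si = 2.0 ** (-(ddct_var - ddct_gene))
        rows.append(
            {
                "patient": patient,
                "ddct_gene": ddct_gene,
                "ddct_variant": ddct_var,
                "fc_gene": 2.0 ** (-ddct_gene),
                "fc_variant": fc,
                "si": si,
            }
        )
    per_patient = pd.DataFrame(rows)
    if per_patient.empty:
        raise ValueError(f"no complete tumour/NAT pairs for assays "
                         f"{gene_assay}/{variant_assay}")
    log2_si = np.log2(per_patient["si"].to_numpy(dtype=float))
    degenerate = False
    if len(per_patient) < 2:
        pval: float | None = None
    elif np.allclose(log2_si, log2_si[0]):
        # all patients identical: the t statistic is undefined; a non-zero
        # constant shift is infinitely significant, a zero shift is null
        degenerate = True
        pval = DEGENERATE_P if abs(log2_si[0]) > 0 else 1.0
    else:
        pval = float(stats.ttest_1samp(log2_si, 0.0).pvalue)
    return EventStats(
        gene=gene or gene_assay,
        per_patient=per_patient,
        median_fc=float(per_patient["fc_variant"].median()),
        median_si=float(per_patient["si"].median()),
        t_pvalue=pval,
        degenerate=degenerate,
    )


def qrt_outcome(
    summary: EventStats,
    hypothesis_direction: int,
    *,
    alpha: float = 0.05,
    si_thresh: float = 2.0,
) -> str:
    """Score one subtype's qRT-PCR evidence as "+" or "-".

    "+" requires the observed direction to agree with the exon-array
    hypothesis and either significance (t-test p <= alpha) or a high
    magnitude (median SI >= si_thresh or <= 1/si_thresh).
    """
    if hypothesis_direction not in (-1, 1):
        raise ValueError("hypothesis_direction must be +1 or -1")
    if summary.direction != hypothesis_direction:
        return "-"
    significant = summary.t_pvalue is not None and summary.t_pvalue <= alpha
    high = summary.median_si >= si_thresh or summary.median_si <= 1.0 / si_thresh
    return "+" if (significant or high) else "-"


def rtpcr_outcome(fraction: str | None) -> str:
    """Score an endpoint RT-PCR result.

    ``"k/n"`` is positive iff k/n > 1/2 (strict majority); ``"-"`` (single
    product, no pattern) is negative; ``None``/``"N/A"`` means the assay
    was not run.
    """
    if fraction is None:
        return "not_available"
    s = str(fraction).strip()
    if s.upper() in ("N/A", "NA", ""):
        return "not_available"
    if s == "-":
        return "negative"
    try:
        k, n = s.split("/")
        k, n = int(k), int(n)
    except ValueError as exc:
        raise ValueError(f"cannot parse RT-PCR fraction {fraction!r}") from exc
    if n < 1:
        raise ValueError(f"invalid RT-PCR denominator in {fraction!r}")
    return "positive" if k / n > 0.5 else "negative"


@dataclass
class ValidationEvent:
    """One hypothesised splicing event and its laboratory evidence."""

    gene: str
    hypothesis: str
    rt_pcr: str | None            # "k/n", "-", or None / "N/A"
    qrt: dict[str, str] = field(default_factory=dict)  # subtype -> "+" / "-"

    @property
    def rt_pcr_call(self) -> str:
        return rtpcr_outcome(self.rt_pcr)


def validation_status(event: ValidationEvent) -> str:
    """Decide validated/devalidated for one event.

    Validated iff at least one subtype scored "+" in qRT-PCR and the
    RT-PCR, where available, shows the pattern in a strict majority of
    patients.
    """
    if not event.qrt:
        raise ValueError(f"event {event.gene}: no qRT-PCR outcome available")
    any_positive = any(v == "+" for v in event.qrt.values())
    rt = event.rt_pcr_call
    if any_positive and rt in ("positive", "not_available"):
        return "validated"
    return "devalidated"


def validate_events(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the decision rule to an event table.

    Expects columns gene, hypothesis, rt_pcr, qrt_AdCa, qrt_SCC; returns
    the table with an appended ``status`` column.
    """
    out = table.copy()
    statuses = []
    for row in table.itertuples(index=False):
        ev = ValidationEvent(
            gene=row.gene,
            hypothesis=row.hypothesis,
            rt_pcr=row.rt_pcr,
            qrt={"AdCa": row.qrt_AdCa, "SCC": row.qrt_SCC},
        )
        statuses.append(validation_status(ev))
    out["status"] = statuses
    return out


def load_reference_validation_table() -> pd.DataFrame:
    """Load the packaged 16-event NSCLC validation worked example.

    Columns: gene, hypothesis, rt_pcr, qrt_AdCa, qrt_SCC,
    expected_status.
    """
    ref = importlib.resources.files("exonflow").joinpath("data/validation_events.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
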