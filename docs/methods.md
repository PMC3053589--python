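# Methods note

This note records the statistical model, the assumptions behind each
stage, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices made in the implementation. Every empirical figure quoted here
is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted beyond what those runs verify.

## 1. Study design and data model

The workflow targets paired designs: each patient contributes one tumour
and one adjacent-normal (NAT) sample, and tumour samples may carry a
subtype label (e.g. AdCa / SCC). Input intensities are linear-scale
probe-level measurements; all modelling is on log2 intensities.

## 2. Chip re-definition

Probe sets are rebuilt from a transcript annotation rather than taken
from a vendor library:

* **Exon collection.** Exon records are read from GTF (1-based inclusive
  coordinates, converted internally to 0-based half-open). Within a
  locus, exons sharing (chrom, start, end, strand) are merged into one
  record keeping all transcript links.
* **PSR construction.** Per locus and strand, exons are split at every
  annotated exon boundary. The resulting probe selection regions (PSRs)
  form an exact base-wise partition of the exon bases: no base is covered
  twice and every PSR boundary is an annotated boundary. This is
  verified against a brute-force partition oracle on random toy loci.
* **Probe mapping.** A probe is assigned to the PSR that fully contains
  its genomic hit. Probes with more than one hit are excluded
  (multi-mapping), as are probes overlapping a repeat interval by one or
  more bases. PSRs that are more than 50% repeat-masked are dropped
  entirely. A probe straddling a PSR boundary follows its midpoint
  (`straddle_rule="midpoint"`, the default) or is dropped
  (`"strict"`).
* **Clusters.** Probe sets are grouped into transcript clusters — the
  connected components of the locus/transcript graph, so a transcript
  annotated across two loci merges them.

Assumption: the annotation is the authority on gene structure; probes
are trusted only where they map uniquely and cleanly.

## 3. Preprocessing

Order of operations: **quantile normalisation → background adjustment →
summarisation**. Background adjustment after normalisation mirrors the
workflow this package implements and is preserved deliberately, although
adjusting before normalising is the more common arrangement; with
well-separated signal and background the difference is small.

* **Quantile normalisation** maps each sample's order statistics to the
  across-sample mean of order statistics. After normalisation every
  column holds the identical multiset of values (tested as an exact
  identity). Caveat: when a large fraction of probes shifts in one
  direction in one group (easy to provoke in small simulations),
  equalising the distributions absorbs part of that shift. This is a
  property of the method, not a defect of the implementation.
* **Background adjustment** subtracts, per sample and GC bin, the mean
  intensity of the labelled background probes in that bin, on the linear
  scale, flooring at 1.0 so the log2 transform stays defined. Bins with
  no background probes fall back to the global background mean with a
  warning.
* **Probe-set summarisation** is median polish on the log2 probe x
  sample matrix (the RMA summarisation step); the probe-set value is
  the overall plus column effect. Max 10 sweeps, convergence tolerance
  1e-6; single-probe sets pass through.
* **Gene summarisation** is a one-step Tukey biweight location estimate
  across the cluster's probe-set values per sample, with c = 5 and
  epsilon = 1e-4 (MAS5-style constants). The biweight matters: it
  resists the one aberrant exon that a splicing event creates, so the
  gene-level contrast is nearly free of the event itself (splicing-index
  recovery bias measured at -0.005 log2 over 200 replicates; an
  unweighted mean would be biased by the affected exon's weight, 1/k).

## 4. Detection above background (DABG) and the background filter

Per sample, the background probes in each GC bin form an empirical null
distribution (bins with fewer than 20 probes are merged into the nearest
populated bin). A probe with intensity x gets the upper-tail rank
p-value `(#background >= x + 1) / (n + 1)`; probe-level p-values are
combined per probe set with Stouffer's method (Fisher available). A
probe set is **present** in a group when p <= 0.01 in at least 75% of
the group's samples (count rounded up). A probe set absent in every
group is removed; a gene left with fewer than five present probe sets
is removed entirely.

Calibration: with probes drawn from the background distribution itself,
the detection p-values are uniform up to the rank-grid discreteness;
tested with a KS test at N = 10^4 p-values, and the fraction below alpha
matches alpha within Monte-Carlo error. Note the error budget: all
probes of a sample share one realized background sample, so the
dominant noise term scales with the background size, not the probe
count. Sensitivity: at a 3-log2 signal/background separation the filter
removed all 76 planted absent probe sets (sensitivity 1.0, requirement
>= 0.95) without collateral loss of expressed probe sets.

## 5. Splicing ANOVA

Per gene (transcript cluster with >= 5 probe sets), the split-plot
mixed model on log2 probe-set expression I:

    I = mu + G + P + E + E*G + S(G*P) + eps

with G the pathology group (fixed), P the patient (fixed block), E the
exon/probe set (fixed), and S the sample, the whole-plot experimental
unit nested in G x P. The two strata are fitted separately:

* **Subplot stratum.** The sample factor absorbs mu + G + P + S(G*P)
  exactly; E and E*G are tested against the residual mean square. The
  E*G interaction p-value (`p_AS`) is the alternative-splicing test.
* **Whole-plot stratum.** Per-sample means follow `mean ~ G + P`; G and
  P are tested against the sample-stratum residual (the S(G*P) mean
  square). Sums of squares are computed on the raw scale (means-scale
  SS times the number of exons) so the two strata share one ANOVA table.

Sums of squares are increments of residual SS between nested column
spaces, computed with orthonormal bases from SVD (rank tolerance
1e-10 relative to the largest singular value). On balanced designs the
increments equal the classical cell-mean formulas (verified to 1e-8
against an independent oracle); on unbalanced designs they are
R(term | all other terms) increments. Degenerate F statistics are
handled explicitly: a numerator SS at roundoff level gives p = 1, a
zero denominator under a real numerator gives the p-value floor 1e-300.
The roundoff threshold is relative, `1e-10 x` the centred total SS —
an absolute tolerance misclassifies exact-zero interactions on data
with a large overall scale.

Calibration and power, measured by the acceptance suite: null `p_AS`
is uniform (KS at N = 10^4 fits); BH at nominal FDR 0.05 over 1000
genes per replicate (5% carrying planted effects) gave mean
false-discovery proportion 0.056, within twice the Monte-Carlo standard
error of the nominal level.

Gene-level and probe-set contrasts come from the reduced model
`I = mu + G + P + eps` by OLS; on balanced paired data the group
contrast `cg` equals the mean per-patient tumour - NAT difference, and
the group F-test equals the paired t-test (both asserted). The
**splicing index** of a probe set is `log2 SI = cg_exon - cg_gene`,
reported alongside `SI = 2^(log2 SI)` — the ratio of the exon's linear
fold change to its gene's. In subtype mode the design's tumour samples
are split by subtype (group levels AdCa / SCC / NAT), per-subtype SIs
are computed on the subtype's patients, and a probe set is flagged
subtype-specific when |delta log2 SI| >= 0.5 between subtypes.

## 6. Candidate selection

* **Primary list**: genes with BH q <= 0.05 on `p_AS`; the realized
  p-value threshold is reported.
* **Sub-list A**: primary genes with group p > 0.05 (splicing without
  expression change), top 100 by the gene's most extreme |log2 SI|.
* **Sub-list B**: primary genes with group p <= 0.05, patient p > 0.2,
  and |log2 gene FC| <= max |log2 SI| (the expression change does not
  exceed the splicing signal; compared as absolute log2 magnitudes),
  top 100 by extreme |log2 SI|.
* **Sub-list C**: genes whose probe sets overlap (>= 1 base,
  strand-aware) a catalogued alternative-splicing event and show
  SI >= 1.4 or <= 1/1.4; restricted to the primary list by default.
* **Final list**: the union A | B | C, with Venn-region counts.

The **delta-log-p diagnostic** quantifies how the background filter
shifts evidence: for genes analysed in both a filtered and an
unfiltered run, `delta = log p_with - log p_without`; the bias-corrected
sample skewness and the D'Agostino skewness-test p-value are reported
(minimum 8 genes). A left-skewed delta distribution means the filter
concentrates improvements in a minority of genes.

## 7. qRT-PCR validation calculus

Technical replicates are averaged on the Ct scale. Each assay is
normalised to the arithmetic mean Ct of the endogenous control assays of
its sample — the geometric mean of the control quantities on the linear
scale. Per patient,

    ddCt = dCt(tumour) - dCt(NAT)
    FC   = 2^(-ddCt)
    SI   = FC_variant / FC_gene = 2^-(ddCt_variant - ddCt_gene)

(the ratio identity holds exactly and is asserted). The significance
test is the one-sample t-test of per-patient log2 SI against zero,
two-sided; zero-variance SI vectors are degenerate (reported p 1e-16
for a non-zero constant shift, 1.0 for an exactly null one). A subtype
scores "+" when the observed direction matches the exon-array
hypothesis and either p <= 0.05 or the median SI is >= 2.0 or <= 0.5.
An endpoint RT-PCR fraction "k/n" is positive iff k/n > 1/2 (strict
majority); "-" is negative; missing assays are `not_available`. An
event is **validated** iff at least one subtype scores "+" and the
RT-PCR call is positive or not available. The packaged 16-event
worked example (`exonflow/data/validation_events.tsv`) reproduces 11
validated / 5 devalidated under this rule, recomputed in the tests.

## 8. Synthetic-data generator

What it emulates: a single-chromosome annotation with 6-10 exons per
gene; cassette-exon events (a second transcript skipping one internal
exon) in a configurable fraction of genes with a log2 splicing shift in
tumour samples; gene-level differential expression; absent exons drawn
at the GC-dependent background level; GC-controlled 25-mer probes (4
per exon) plus labelled background probes spanning the GC range;
cross-hybridising probes (hit count 2, intensity offset); patient
effects; i.i.d. Gaussian log2 noise; matched qPCR Ct tables (Ct falls
one cycle per two-fold expression) and endpoint RT-PCR fractions.

What it does not emulate: optical noise and spatial artefacts,
probe-affinity sequence models beyond the GC tally, partial exon
usage / intron retention / alternative 5'-3' ends, correlated noise
between probes of an exon, RNA degradation, or batch effects.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `baseline_mean` | 10.0 log2 | expressed exons must sit well above the GC background (4-6 log2). At small separations the linear-scale background subtraction compresses the log2 signal nonlinearly per sample, which imitates exon-by-group interaction and inflates the residual; at ~5 log2 separation the distortion is ~0.04 log2 and negligible. |
| `probe_noise_sd` | 0.25 | typical log2 residual scale for expressed probes |
| `patient_sd` | 0.5 | patient effects larger than noise, so the paired design matters |
| `splicing_log2_effect` | 1.0 | a two-fold inclusion shift, detectable but not trivial at 6 pairs |
| `background_mean_by_gc` | 4.0 + 0.08 x GC | monotone GC dependence so the GC-binned background model is exercised |
| `probes_per_exon` | 4 | exon-array-like probe-set size |
| `n_patients` | 6 | smallest size at which the split-plot F-tests have usable power |

Determinism: every random stream is derived from the seed via a CRC32
label hash into `SeedSequence` spawn keys, so runs are reproducible
across processes (Python's salted `hash()` is not used). Identical
configurations produce byte-identical output files (tested).

## 9. Numerical choices

* Projections via SVD orthonormal bases (stable under rank deficiency);
  per-design bases are cached, making a gene fit ~1.4 ms and the
  10^4-gene null calibration feasible.
* Rank p-values use `(r + 1) / (n + 1)`, never exactly zero; combined
  p-values are clipped to [1e-12, 1].
* Median polish operates on log2 values; quantile normalisation and
  background subtraction on the linear scale.
* BH q-values come from `statsmodels.stats.multitest.multipletests`;
  skewness and its test from `scipy.stats` (`bias=False`, D'Agostino,
  n >= 8).
* All outputs are plain text (TSV / JSON / YAML); the chip definition
  round-trips exactly through its PGF-dialect text format.

## 10. Limitations

* The fixed-effects split-plot treatment of patients assumes
  homoscedastic residuals across exons; no per-exon variance model.
* Exact F-tests hold for balanced paired designs; unbalanced designs
  fall back to partial-SS increments whose null distribution is
  approximate under the mixed design.
* The probe-set model ignores probe-level affinity differences once
  median polish has summarised them; strongly non-additive probe
  behaviour leaks into the residual.
* Sub-list C depends on the completeness of the supplied catalogue of
  known events.
* The qRT-PCR rule inherits the arbitrariness of its thresholds
  (alpha 0.05, SI 2.0, strict majority); they are surfaced as
  configuration, not hidden.
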