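"""Tests of the split-plot splicing ANOVA and its Results object."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonflow.anova import (
    DesignError,
    SplicingAnova,
    bh_fdr,
    fit_gene_mlm,
    fit_probeset_mlm,
    run_splicing_analysis,
    splicing_index,
)
from exonflow.simulate import simulate_gene_block

from conftest import make_design
from oracles import balanced_splitplot_ss, lstsq_splitplot_ss


def block_from(values, design):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"PS{i:03d}" for i in range(values.shape[0])],
        columns=design["sample"].tolist(),
    )


class TestGeneModelOracle:
    def test_balanced_ss_match_cell_mean_formulas(self, design6):
        rng = np.random.default_rng(5)
        for rep in range(20):
            k = int(rng.integers(2, 9))
            block = simulate_gene_block(
                k, design6, log2_si=rng.normal(), affected_exon=0,
                de_log2_fc=rng.normal(), rng=rng,
            )
            fit = fit_gene_mlm(block, design6)
            oracle = balanced_splitplot_ss(block, design6)
            for term, ss in oracle.items():
                assert fit.ss[term] == pytest.approx(ss, abs=1e-8), term

    def test_balanced_degrees_of_freedom(self, design6):
        block = simulate_gene_block(8, design6, rng=np.random.default_rng(0))
        fit = fit_gene_mlm(block, design6)
        # 6 patients x 2 pathologies, 8 exons
        assert fit.df == {
            "G": 1, "P": 5, "E": 7, "E:G": 7,
            "S(G*P)": 5, "residual": 7 * 10,
        }

    def test_unbalanced_ss_match_lstsq_oracle(self, design6):
        rng = np.random.default_rng(9)
        design = design6.iloc[:-1].reset_index(drop=True)  # drop one NAT
        block = simulate_gene_block(6, design, log2_si=0.8, rng=rng)
        fit = fit_gene_mlm(block, design)
        oracle = lstsq_splitplot_ss(block, design)
        for term, ss in oracle.items():
            assert fit.ss[term] == pytest.approx(ss, abs=1e-8), term

    def test_pure_exon_effect_gives_null_interaction(self, design6):
        # exon profile identical in every sample: SS(E:G) = 0 exactly
        exon_eff = np.arange(5, dtype=float)
        block = block_from(np.tile(exon_eff[:, None], (1, 12)) + 8.0, design6)
        fit = fit_gene_mlm(block, design6)
        assert fit.ss["E:G"] == pytest.approx(0.0, abs=1e-10)
        assert fit.p_AS == 1.0
        assert fit.ss["E"] == pytest.approx(12 * ((exon_eff - 2) ** 2).sum(), abs=1e-8)

    def test_planted_interaction_detected(self, design6):
        block = simulate_gene_block(
            8, design6, log2_si=1.0, affected_exon=2,
            rng=np.random.default_rng(1),
        )
        fit = fit_gene_mlm(block, design6)
        assert fit.p_AS < 1e-6

    def test_gene_level_shift_not_flagged_as_splicing(self, design6):
        fits = [
            fit_gene_mlm(
                simulate_gene_block(8, design6, de_log2_fc=2.0,
                                    rng=np.random.default_rng(s)),
                design6,
            )
            for s in range(30)
        ]
        p_as = np.array([f.p_AS for f in fits])
        p_g = np.array([f.p_G for f in fits])
        assert (p_as < 0.05).mean() <= 0.2  # null-ish interaction
        assert (p_g < 0.05).mean() >= 0.9   # strong group effect

    def test_patient_shift_invariance(self, design6):
        rng = np.random.default_rng(3)
        block = simulate_gene_block(6, design6, log2_si=0.5, rng=rng)
        fit1 = fit_gene_mlm(block, design6)
        shifted = block.copy()
        for patient, sub in design6.groupby("patient"):
            shifted[sub["sample"].tolist()] += hash(patient) % 7
        fit2 = fit_gene_mlm(shifted, design6)
        assert fit2.p_AS == pytest.approx(fit1.p_AS, rel=1e-9)
        assert fit2.ss["E:G"] == pytest.approx(fit1.ss["E:G"], abs=1e-8)
        assert fit2.ss["residual"] == pytest.approx(fit1.ss["residual"], abs=1e-8)

    def test_null_pvalues_uniform(self, design6):
        rng = np.random.default_rng(17)
        p = np.array([
            fit_gene_mlm(simulate_gene_block(8, design6, rng=rng), design6).p_AS
            for _ in range(300)
        ])
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_design_errors(self, design6):
        block = simulate_gene_block(4, design6, rng=np.random.default_rng(0))
        with pytest.raises(DesignError, match="two probe sets"):
            fit_gene_mlm(block.iloc[:1], design6)
        one_group = design6.assign(pathology="tumour")
        with pytest.raises(DesignError, match="two levels"):
            fit_gene_mlm(block, one_group)
        one_patient = design6.assign(patient="P01")
        with pytest.raises(DesignError):
            fit_gene_mlm(block, one_patient)


class TestProbesetContrast:
    def paired_design(self, n):
        return pd.DataFrame({
            "sample": [f"P{i}_{a}" for i in range(n) for a in ("T", "N")],
            "patient": [f"P{i}" for i in range(n) for _ in range(2)],
            "pathology": ["tumour", "NAT"] * n,
        })

    def test_two_patient_worked_example(self):
        design = self.paired_design(2)
        values = pd.Series([2.0, 1.0, 4.0, 3.0], index=design["sample"])
        c = fit_probeset_mlm(values, design)
        assert c.cg == pytest.approx(1.0)

    def test_equals_mean_paired_difference(self):
        rng = np.random.default_rng(2)
        design = self.paired_design(6)
        values = pd.Series(rng.normal(8, 1, 12), index=design["sample"])
        c = fit_probeset_mlm(values, design)
        diffs = [
            values[f"P{i}_T"] - values[f"P{i}_N"] for i in range(6)
        ]
        assert c.cg == pytest.approx(np.mean(diffs), abs=1e-10)

    def test_patient_shift_invariance(self):
        rng = np.random.default_rng(4)
        design = self.paired_design(5)
        values = pd.Series(rng.normal(8, 1, 10), index=design["sample"])
        shifted = values.copy()
        for i in range(5):
            shifted[[f"P{i}_T", f"P{i}_N"]] += i * 3.0
        c1, c2 = fit_probeset_mlm(values, design), fit_probeset_mlm(shifted, design)
        assert c2.cg == pytest.approx(c1.cg, abs=1e-10)
        assert c2.p_G == pytest.approx(c1.p_G, rel=1e-9)

    def test_p_g_matches_paired_ttest(self):
        # on balanced paired data the group F-test equals the paired t-test
        rng = np.random.default_rng(8)
        design = self.paired_design(6)
        values = pd.Series(rng.normal(8, 1, 12), index=design["sample"])
        c = fit_probeset_mlm(values, design)
        t = stats.ttest_rel(
            [values[f"P{i}_T"] for i in range(6)],
            [values[f"P{i}_N"] for i in range(6)],
        )
        assert c.p_G == pytest.approx(t.pvalue, rel=1e-9)

    def test_single_group_raises(self):
        design = self.paired_design(2).assign(pathology="tumour")
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=design["sample"])
        with pytest.raises(DesignError):
            fit_probeset_mlm(values, design)


class TestSplicingIndex:
    def test_closed_forms(self):
        log2_si, si = splicing_index(1.5, 0.0)
        assert (log2_si, si) == (1.5, pytest.approx(2.0**1.5))
        log2_si, si = splicing_index(0.5, 2.0)
        assert log2_si == -1.5
        assert si == pytest.approx(0.3535533905932738)
        assert splicing_index(1.0, 1.0) == (0.0, 1.0)

    def test_invariant_to_gene_wide_fold_change(self):
        # adding the same DE shift to exon and gene contrasts cancels
        for shift in (-2.0, 0.0, 3.7):
            assert splicing_index(0.8 + shift, 0.1 + shift)[0] == pytest.approx(0.7)

    def test_reciprocal_symmetry(self):
        l1, s1 = splicing_index(1.0, 0.0)
        l2, s2 = splicing_index(-1.0, 0.0)
        assert l1 == -l2 and s1 == pytest.approx(1 / s2)


class TestBhFdr:
    def test_hand_worked_example(self):
        q, threshold = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), fdr=0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])
        assert threshold == pytest.approx(0.03)

    def test_nothing_significant(self):
        q, threshold = bh_fdr(np.array([0.5, 0.8]), fdr=0.05)
        assert threshold is None
        np.testing.assert_allclose(q, [0.8, 0.8])

    def test_empty_input(self):
        q, threshold = bh_fdr(np.array([]))
        assert q.size == 0 and threshold is None

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=50))
        q, _ = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


def subtype_design(n_per_subtype=3):
    rows = []
    i = 0
    for st in ("AdCa", "SCC"):
        for _ in range(n_per_subtype):
            i += 1
            rows.append((f"P{i:02d}_T", f"P{i:02d}", "tumour", st))
            rows.append((f"P{i:02d}_N", f"P{i:02d}", "NAT", st))
    return pd.DataFrame(rows, columns=["sample", "patient", "pathology", "subtype"])


def synthetic_expression(design, n_genes=3, n_ps=6, si_by_subtype=None,
                         gene="G1", exon=0, seed=0):
    """Small probe-set/gene expression matrices with one optional event."""
    rng = np.random.default_rng(seed)
    ps_rows, ps_index, ps2gene = [], [], {}
    tumour = design["pathology"].to_numpy() == "tumour"
    for g in range(n_genes):
        gid = f"G{g + 1}"
        for e in range(n_ps):
            psid = f"{gid}:PS{e:03d}"
            ps2gene[psid] = gid
            ps_index.append(psid)
            vals = 8.0 + 0.05 * rng.standard_normal(len(design))
            if si_by_subtype and gid == gene and e == exon:
                for st, si in si_by_subtype.items():
                    mask = tumour & (design["subtype"].to_numpy() == st)
                    vals[mask] += si
            ps_rows.append(vals)
    expr_ps = pd.DataFrame(ps_rows, index=ps_index, columns=design["sample"].tolist())
    expr_gene = pd.DataFrame(
        [expr_ps.loc[[p for p in ps_index if p.startswith(f"G{g + 1}:")]].mean()
         for g in range(n_genes)],
        index=[f"G{g + 1}" for g in range(n_genes)],
    )
    return expr_ps, expr_gene, ps2gene


class TestSplicingAnovaModel:
    def test_pathology_mode_end_to_end(self):
        design = subtype_design(3)
        expr_ps, expr_gene, ps2gene = synthetic_expression(
            design, si_by_subtype={"AdCa": 1.0, "SCC": 1.0}, seed=1
        )
        res = run_splicing_analysis(expr_ps, expr_gene, design, ps2gene)
        assert res.mode == "pathology"
        assert list(res.gene_table.index) == ["G1", "G2", "G3"]
        assert res.gene_table.loc["G1", "p_AS"] < 1e-4
        assert (res.gene_table.loc[["G2", "G3"], "p_AS"] > 0.01).all()
        # the affected probe set carries the extreme SI
        assert res.probeset_table["log2_si"].abs().idxmax() == "G1:PS000"
        assert res.gene_table.loc["G1", "max_abs_log2_si"] == pytest.approx(
            res.probeset_table.loc["G1:PS000", "log2_si"], abs=1e-9
        )
        assert "significant genes" in res.summary()

    def test_si_equals_exon_minus_gene_contrast(self):
        design = subtype_design(3)
        expr_ps, expr_gene, ps2gene = synthetic_expression(
            design, si_by_subtype={"AdCa": 1.0, "SCC": 1.0}, seed=2
        )
        res = run_splicing_analysis(expr_ps, expr_gene, design, ps2gene)
        for psid, row in res.probeset_table.iterrows():
            cg_gene = res.gene_table.loc[row["gene"], "cg_gene"]
            assert row["log2_si"] == pytest.approx(row["cg"] - cg_gene, abs=1e-10)
            assert row["si"] == pytest.approx(2.0 ** row["log2_si"], rel=1e-12)

    def test_subtype_mode_flags_differential_event(self):
        design = subtype_design(4)
        expr_ps, expr_gene, ps2gene = synthetic_expression(
            design, si_by_subtype={"AdCa": 1.2, "SCC": 0.0}, seed=3
        )
        model = SplicingAnova(expr_ps, expr_gene, design, ps2gene,
                              mode="subtype", min_probe_sets=5)
        res = model.fit()
        row = res.probeset_table.loc["G1:PS000"]
        assert row["subtype_specific"]
        # the gene summary averages all 6 probe sets including the affected
        # one, so a planted shift of 1.2 appears as SI = 1.2 * 5/6 = 1.0
        assert row["delta_log2_si"] == pytest.approx(1.0, abs=0.15)
        assert row["log2_si_AdCa"] == pytest.approx(1.0, abs=0.15)
        assert row["log2_si_SCC"] == pytest.approx(0.0, abs=0.15)

    def test_subtype_mode_shared_event_not_flagged(self):
        design = subtype_design(4)
        expr_ps, expr_gene, ps2gene = synthetic_expression(
            design, si_by_subtype={"AdCa": 1.0, "SCC": 1.0}, seed=4
        )
        res = SplicingAnova(expr_ps, expr_gene, design, ps2gene,
                            mode="subtype").fit()
        assert not res.probeset_table["subtype_specific"].any()

    def test_pathology_mode_ignores_subtype_column(self):
        design = subtype_design(3)
        expr_ps, expr_gene, ps2gene = synthetic_expression(
            design, si_by_subtype={"AdCa": 1.0, "SCC": 1.0}, seed=5
        )
        res1 = run_splicing_analysis(expr_ps, expr_gene, design, ps2gene)
        res2 = run_splicing_analysis(
            expr_ps, expr_gene, design.drop(columns="subtype"), ps2gene
        )
        pd.testing.assert_frame_equal(res1.gene_table, res2.gene_table)

    def test_min_probe_sets_excludes_short_genes(self):
        design = subtype_design(3)
        expr_ps, expr_gene, ps2gene = synthetic_expression(design, n_ps=4, seed=6)
        res = run_splicing_analysis(expr_ps, expr_gene, design, ps2gene,
                                    min_probe_sets=5)
        assert len(res.gene_table) == 0

    def test_mode_validation(self):
        design = subtype_design(2)
        expr_ps, expr_gene, ps2gene = synthetic_expression(design, seed=0)
        with pytest.raises(ValueError):
            SplicingAnova(expr_ps, expr_gene, design, ps2gene, mode="other")
        with pytest.raises(DesignError):
            SplicingAnova(expr_ps, expr_gene, design.drop(columns="subtype"),
                          ps2gene, mode="subtype")

    def test_results_write(self, tmp_path):
        design = subtype_design(3)
        expr_ps, expr_gene, ps2gene = synthetic_expression(design, seed=7)
        res = run_splicing_analysis(expr_ps, expr_gene, design, ps2gene)
        res.write(tmp_path)
        genes = pd.read_csv(tmp_path / "genes.tsv", sep="\t", index_col=0)
        assert list(genes.index) == list(res.gene_table.index)
        assert (tmp_path / "probe_sets.tsv").exists()
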