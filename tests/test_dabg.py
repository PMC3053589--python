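"""Tests of detection-above-background calls and the background filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonflow.chipdef import ChipDefinition, GenomicInterval, ProbeSet
from exonflow.dabg import (
    BackgroundModel,
    apply_background_filter,
    dabg_pvalues,
    fit_background_model,
    present_calls,
)


def seq_for_gc(gc, length=25):
    return "G" * gc + "A" * (length - gc)


def chip_with_sets(sets):
    """Chip containing the given {probeset_id: [(probe_id, gc), ...]}."""
    chip = ChipDefinition()
    pos = 100
    for psid, members in sets.items():
        chip.probe_sets[psid] = ProbeSet(
            psr_id=psid, probeset_id=psid,
            probe_ids=tuple(pid for pid, _ in members),
        )
        for pid, gc in members:
            chip.probes[pid] = (
                GenomicInterval("chr1", pos, pos + 25), seq_for_gc(gc)
            )
            pos += 50
    return chip


def bg_frame(values, prefix="bg"):
    values = np.asarray(values, dtype=float)
    idx = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=idx, columns=cols)


class TestBackgroundModel:
    def test_distributions_sorted_per_bin(self):
        raw = bg_frame([[5.0], [3.0], [4.0], [10.0], [8.0]])
        gc = {"bg0": 10, "bg1": 10, "bg2": 10, "bg3": 12, "bg4": 12}
        model = fit_background_model(raw, list(raw.index), gc, min_bin_size=2)
        np.testing.assert_allclose(model.distributions["s0"][10], [3.0, 4.0, 5.0])
        np.testing.assert_allclose(model.distributions["s0"][12], [8.0, 10.0])

    def test_sparse_bin_merged_with_warning(self):
        raw = bg_frame(np.arange(1, 12, dtype=float)[:, None])
        gc = {f"bg{i}": (10 if i < 10 else 20) for i in range(11)}
        with pytest.warns(UserWarning, match="merged"):
            model = fit_background_model(raw, list(raw.index), gc, min_bin_size=5)
        assert model.bin_of[20] == 10
        assert len(model.lookup("s0", 20)) == 11

    def test_unknown_gc_uses_nearest_bin(self):
        raw = bg_frame([[1.0], [2.0], [30.0], [40.0]])
        gc = {"bg0": 8, "bg1": 8, "bg2": 16, "bg3": 16}
        model = fit_background_model(raw, list(raw.index), gc, min_bin_size=2)
        np.testing.assert_allclose(model.lookup("s0", 9), [1.0, 2.0])
        np.testing.assert_allclose(model.lookup("s0", 18), [30.0, 40.0])

    def test_no_background_probes_raises(self):
        with pytest.raises(ValueError):
            fit_background_model(bg_frame([[1.0]]), ["missing"], {})


class TestProbeSetPvalues:
    def test_rank_pvalue_worked_example(self):
        # 999 background values 1..999; a probe at 999.5 beats all of them:
        # p = (0 + 1)/(999 + 1) = 0.001; at 0.5 p = 1000/1000 = 1
        bg = bg_frame(np.arange(1.0, 1000.0)[:, None])
        gc = {p: 12 for p in bg.index}
        gc.update({"pm1": 12, "pm2": 12})
        model = fit_background_model(bg, list(bg.index), gc)
        chip = chip_with_sets({"PS1": [("pm1", 12)], "PS2": [("pm2", 12)]})
        raw = pd.DataFrame({"s0": [999.5, 0.5]}, index=["pm1", "pm2"])
        calls = dabg_pvalues(raw, model, chip)
        assert calls.p.loc["PS1", "s0"] == pytest.approx(0.001)
        assert calls.p.loc["PS2", "s0"] == pytest.approx(1.0)

    def test_tie_counts_as_greater_equal(self):
        bg = bg_frame([[10.0], [20.0], [30.0], [40.0]])
        gc = {p: 12 for p in bg.index}
        gc["pm1"] = 12
        model = fit_background_model(bg, list(bg.index), gc, min_bin_size=2)
        chip = chip_with_sets({"PS1": [("pm1", 12)]})
        raw = pd.DataFrame({"s0": [30.0]}, index=["pm1"])
        calls = dabg_pvalues(raw, model, chip)
        # two background values >= 30 -> p = 3/5
        assert calls.p.loc["PS1", "s0"] == pytest.approx(3 / 5)

    def test_stouffer_strengthens_with_probe_count(self):
        # identical per-probe evidence p=0.1: combined p drops as k grows
        bg = bg_frame(np.arange(1.0, 1000.0)[:, None])
        gc = {p: 12 for p in bg.index}
        x = 899.5  # 100 of 999 background values above -> p ~ 0.101
        pvals = {}
        for k in (1, 2, 4):
            chip = chip_with_sets({"PS": [(f"pm{i}", 12) for i in range(k)]})
            gc.update({f"pm{i}": 12 for i in range(k)})
            model = fit_background_model(bg, list(bg.index), gc)
            raw = pd.DataFrame({"s0": [x] * k}, index=[f"pm{i}" for i in range(k)])
            pvals[k] = dabg_pvalues(raw, model, chip).p.loc["PS", "s0"]
        assert pvals[4] < pvals[2] < pvals[1] < 0.2
        # closed form: Phi(sqrt(k) * z_p)
        z = stats.norm.isf(101 / 1000)
        for k in (1, 2, 4):
            assert pvals[k] == pytest.approx(stats.norm.sf(np.sqrt(k) * z), rel=1e-6)

    def test_fisher_method_agrees_in_direction(self):
        bg = bg_frame(np.arange(1.0, 1000.0)[:, None])
        gc = {p: 12 for p in bg.index}
        gc.update({"pm0": 12, "pm1": 12})
        model = fit_background_model(bg, list(bg.index), gc)
        chip = chip_with_sets({"PS": [("pm0", 12), ("pm1", 12)]})
        raw = pd.DataFrame({"s0": [999.5, 999.5]}, index=["pm0", "pm1"])
        st_p = dabg_pvalues(raw, model, chip, method="stouffer").p.iloc[0, 0]
        fi_p = dabg_pvalues(raw, model, chip, method="fisher").p.iloc[0, 0]
        assert st_p < 0.01 and fi_p < 0.01
        with pytest.raises(ValueError):
            dabg_pvalues(raw, model, chip, method="bonferroni")

    def test_pvalues_monotone_in_intensity(self):
        rng = np.random.default_rng(3)
        bg = bg_frame(rng.lognormal(4, 0.5, size=(500, 1)))
        gc = {p: 12 for p in bg.index}
        gc.update({f"pm{i}": 12 for i in range(20)})
        model = fit_background_model(bg, list(bg.index), gc)
        chip = chip_with_sets({f"PS{i}": [(f"pm{i}", 12)] for i in range(20)})
        xs = np.linspace(10, 500, 20)
        raw = pd.DataFrame({"s0": xs}, index=[f"pm{i}" for i in range(20)])
        calls = dabg_pvalues(raw, model, chip)
        p = calls.p.loc[[f"PS{i}" for i in range(20)], "s0"].to_numpy()
        assert (np.diff(p) <= 1e-12).all()

    def test_null_pvalues_uniform_fraction(self):
        # probes drawn from the background distribution itself: the
        # fraction with p <= alpha matches alpha within 3 binomial sigma
        rng = np.random.default_rng(11)
        n_bg, n_pm = 2000, 40_000
        pool = rng.lognormal(4, 0.6, size=n_bg + n_pm)
        bg = bg_frame(pool[:n_bg, None])
        gc = {p: 12 for p in bg.index}
        pm_ids = [f"pm{i}" for i in range(n_pm)]
        gc.update({p: 12 for p in pm_ids})
        model = fit_background_model(bg, list(bg.index), gc)
        chip = chip_with_sets({f"PS{i}": [(pm_ids[i], 12)] for i in range(n_pm)})
        raw = pd.DataFrame({"s0": pool[n_bg:]}, index=pm_ids)
        p = dabg_pvalues(raw, model, chip).p["s0"].to_numpy()
        for alpha in (0.01, 0.05, 0.25):
            frac = (p <= alpha).mean()
            # all probes are ranked against the same realized background
            # sample, so the error is dominated by the sampling noise of the
            # background's empirical tail quantile (scale 1/sqrt(n_bg)),
            # plus the binomial part and the rank-grid discreteness
            sigma = np.sqrt(alpha * (1 - alpha) * (1 / n_bg + 1 / n_pm))
            assert abs(frac - alpha) < 3 * sigma + 1 / (n_bg + 1)


class TestPresentCalls:
    def design(self):
        return pd.DataFrame({
            "sample": [f"s{i}" for i in range(8)],
            "pathology": ["tumour"] * 4 + ["NAT"] * 4,
        })

    def p_table(self, tumour_hits, nat_hits):
        row = [0.001] * tumour_hits + [0.5] * (4 - tumour_hits)
        row += [0.001] * nat_hits + [0.5] * (4 - nat_hits)
        return pd.DataFrame([row], index=["PS1"], columns=[f"s{i}" for i in range(8)])

    def test_threshold_count_is_ceiling(self):
        # 75% of 4 samples = 3 exactly; 3 hits is present, 2 is not
        present = present_calls(self.p_table(3, 0), self.design())
        assert bool(present.loc["PS1", "tumour"]) is True
        assert bool(present.loc["PS1", "NAT"]) is False
        present = present_calls(self.p_table(2, 0), self.design())
        assert bool(present.loc["PS1", "tumour"]) is False

    def test_ceil_vs_floor_rounding(self):
        design = pd.DataFrame({
            "sample": [f"s{i}" for i in range(5)],
            "pathology": ["tumour"] * 5,
        })
        p = pd.DataFrame([[0.001] * 3 + [0.5] * 2], index=["PS1"],
                         columns=[f"s{i}" for i in range(5)])
        # 0.75*5 = 3.75: ceil needs 4 (absent), floor needs 3 (present)
        assert not present_calls(p, design, rounding="ceil").loc["PS1", "tumour"]
        assert present_calls(p, design, rounding="floor").loc["PS1", "tumour"]
        with pytest.raises(ValueError):
            present_calls(p, design, rounding="round")

    def test_boundary_p_equal_alpha_counts(self):
        design = self.design()
        p = self.p_table(4, 0)
        p.loc["PS1", ["s0", "s1", "s2", "s3"]] = 0.01  # exactly alpha
        present = present_calls(p, design, alpha=0.01)
        assert bool(present.loc["PS1", "tumour"]) is True

    def test_subtype_groups(self):
        design = pd.DataFrame({
            "sample": [f"s{i}" for i in range(8)],
            "group": ["AdCa"] * 2 + ["SCC"] * 2 + ["NAT"] * 4,
        })
        p = self.p_table(2, 0)  # hits fall in the two AdCa samples
        present = present_calls(p, design, group_col="group")
        assert set(present.columns) == {"AdCa", "SCC", "NAT"}
        assert bool(present.loc["PS1", "AdCa"]) is True
        assert bool(present.loc["PS1", "SCC"]) is False


class TestBackgroundFilter:
    def test_filter_composition_rules(self):
        # gene A: 5 probe sets present somewhere -> retained
        # gene B: 4 of 6 present -> gene removed, absent sets removed
        present = pd.DataFrame(
            {
                "tumour": [True] * 5 + [True, True, False, False, False, False],
                "NAT": [False] * 5 + [False, True, True, True, False, False],
            },
            index=[f"A:PS{i}" for i in range(5)] + [f"B:PS{i}" for i in range(6)],
        )
        ps2gene = {ps: ps.split(":")[0] for ps in present.index}
        report = apply_background_filter(present, ps2gene, min_present_probe_sets=5)
        assert report.removed_genes == ["B"]
        assert report.retained_genes == ["A"]
        assert report.removed_probe_sets == ["B:PS4", "B:PS5"]
        assert report.retained_probe_sets == sorted(f"A:PS{i}" for i in range(5))
        assert report.to_dict()["n_removed_probe_sets"] == 2

    def test_present_in_any_group_survives_probeset_filter(self):
        present = pd.DataFrame(
            {"tumour": [False], "NAT": [True]}, index=["G:PS0"]
        )
        report = apply_background_filter(present, {"G:PS0": "G"},
                                         min_present_probe_sets=1)
        assert report.removed_probe_sets == []
        assert report.retained_genes == ["G"]

    def test_integration_absent_exons_called_absent(self, sim_parts, sim_chipdef):
        annotation, truth, design, probes, raw = sim_parts
        chip = sim_chipdef
        gc = {
            r.probe_id: r.sequence.count("G") + r.sequence.count("C")
            for r in probes.itertuples()
        }
        bg_ids = list(probes.loc[probes["probe_type"] == "background", "probe_id"])
        model = fit_background_model(raw, bg_ids, gc)
        calls = dabg_pvalues(raw, model, chip)
        present = present_calls(calls.p, design)
        # probe sets of expressed exons are present, absent-exon sets are not
        psr_exons = {
            ps.probeset_id: chip.psrs[ps.psr_id].source_exon_ids
            for ps in chip.probe_sets.values()
        }
        n_checked = 0
        for psid, exons in psr_exons.items():
            if psid not in present.index:
                continue
            if exons & set(truth.absent_exons):
                assert not present.loc[psid].any(), psid
            else:
                assert present.loc[psid].all(), psid
            n_checked += 1
        assert n_checked > 20
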