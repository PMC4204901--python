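"""Generator correctness: determinism, planted effects, truth consistency."""

import numpy as np
import pandas as pd
import pytest

from pcx.core import DataError
from pcx.simulate import (SimulationConfig, simulate_chromatin, simulate_cohort,
                          simulate_expression, simulate_genome,
                          simulate_methylation)


def small_config(**kw):
    base = dict(seed=0, n_genes=40, n_prc2_targets=16,
                genome_length=2_000_000, cpg_density=2.0,
                reads_per_sample=20_000)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_prc2_targets": 50, "n_genes": 40},
        {"mean_coverage": 0},
        {"meth_beta_dispersion": 1.5},
        {"genotypes": {"wt": 1.5}},
        {"n_rrbs_replicates": 0},
    ])
    def test_invalid_configs_raise(self, kw):
        with pytest.raises(DataError):
            small_config(**kw)


class TestGenome:
    def test_empty_case(self):
        ann, cpgs, truth = simulate_genome(small_config(n_genes=0,
                                                        n_prc2_targets=0))
        assert len(ann) == 0 and len(cpgs) == 0

    def test_determinism_same_seed(self):
        a = simulate_genome(small_config(seed=7))
        b = simulate_genome(small_config(seed=7))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_different_seed_differs(self):
        a = simulate_genome(small_config(seed=7))
        b = simulate_genome(small_config(seed=8))
        assert not a[1].equals(b[1])

    def test_cpg_count_tracks_density_by_recount(self):
        cfg = small_config(n_genes=200, n_prc2_targets=80,
                           genome_length=2_000_000, cpg_density=10.0)
        _, cpgs, _ = simulate_genome(cfg)
        # independent recount of emitted positions
        recount = len(np.unique(cpgs["pos"].to_numpy()))
        assert recount == len(cpgs)
        assert abs(recount - 20_000) <= 0.05 * 20_000

    def test_gene_bodies_do_not_overlap(self):
        ann, _, _ = simulate_genome(small_config())
        ordered = ann.sort_values("start")
        assert (ordered["start"].to_numpy()[1:]
                >= ordered["end"].to_numpy()[:-1]).all()

    def test_capacity_error_for_tiny_genome(self):
        with pytest.raises(DataError):
            simulate_genome(small_config(genome_length=50_000))


class TestChromatin:
    def test_full_retention_reproduces_wt_region_set(self):
        cfg = small_config(genotypes={"wt": 1.0, "mut": 1.0})
        ann, _, truth = simulate_genome(cfg)
        regions, _, region_truth, _ = simulate_chromatin(ann, truth, cfg)
        pd.testing.assert_frame_equal(regions[("wt", "d0", "k27")],
                                      regions[("mut", "d0", "k27")])
        assert (region_truth["status"] == "maintained").all()

    def test_zero_retention_loses_everything(self):
        cfg = small_config(genotypes={"wt": 1.0, "null": 0.0})
        ann, _, truth = simulate_genome(cfg)
        regions, _, region_truth, _ = simulate_chromatin(ann, truth, cfg)
        assert len(regions[("null", "d0", "k27")]) == 0
        assert (region_truth["status"] == "lost").all()

    def test_intermediate_retention_within_binomial_interval(self):
        cfg = SimulationConfig(seed=3, n_genes=500, n_prc2_targets=400,
                               genome_length=20_000_000, cpg_density=0.5,
                               reads_per_sample=5_000,
                               genotypes={"wt": 1.0, "hypo": 0.5})
        ann, _, truth = simulate_genome(cfg)
        _, _, region_truth, _ = simulate_chromatin(ann, truth, cfg)
        kept = (region_truth["status"] == "maintained").sum()
        # binomial(400, 0.5) 99% interval
        assert abs(kept - 200) < 2.58 * np.sqrt(400 * 0.25) + 1

    def test_bivalent_promoters_have_both_marks_in_wt(self, cohort):
        truth = cohort.truth["genes"]
        k27 = cohort.region_sets[("wt", "d0", "k27")]
        k4 = cohort.region_sets[("wt", "d0", "k4")]
        targets = set(truth.loc[truth["is_prc2_target"], "gene_id"])
        assert set(k27["name"]) == targets
        assert targets <= set(k4["name"])


class TestMethylation:
    def _meth_setup(self, **kw):
        cfg = small_config(**kw)
        ann, cpgs, truth = simulate_genome(cfg)
        regions, _, region_truth, _ = simulate_chromatin(ann, truth, cfg)
        tables, cpg_truth = simulate_methylation(cpgs, regions, region_truth,
                                                 cfg)
        return cfg, tables, cpg_truth

    def test_null_delta_means_no_genotype_difference(self):
        cfg, tables, cpg_truth = self._meth_setup(
            meth_gain_delta=0.0, genotypes={"wt": 1.0, "null": 0.0})
        lost = cpg_truth["gains_null"].to_numpy()
        assert lost.sum() > 50
        wt = tables[("wt", "d0")]
        mut = tables[("null", "d0")]
        d = (mut.percent(mut.samples[0])[lost]
             - wt.percent(wt.samples[0])[lost])
        d = d[~np.isnan(d)]
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean()) < 4 * se

    def test_planted_gain_recovered_at_analytic_mean(self):
        cfg, tables, cpg_truth = self._meth_setup(
            meth_gain_delta=15.0, mean_coverage=30,
            genotypes={"wt": 1.0, "null": 0.0},
            cpg_density=4.0)
        lost = cpg_truth["gains_null"].to_numpy()
        assert lost.sum() >= 1000
        wt = tables[("wt", "d0")]
        mut = tables[("null", "d0")]
        d = (mut.percent(mut.samples[0])[lost]
             - wt.percent(wt.samples[0])[lost])
        d = d[~np.isnan(d)]
        # analytic beta-binomial mean difference is exactly the planted delta
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert d.mean() == pytest.approx(15.0, abs=4 * se)

    def test_replicates_correlate_strongly(self):
        cfg, tables, _ = self._meth_setup(genotypes={"wt": 1.0})
        t = tables[("wt", "d0")]
        p1 = t.percent(t.samples[0])
        p2 = t.percent(t.samples[1])
        ok = ~(np.isnan(p1) | np.isnan(p2))
        r = np.corrcoef(p1[ok], p2[ok])[0, 1]
        assert r > 0.9

    def test_truth_consistency_gains_only_in_lost_regions(self, cohort):
        cpg_truth = cohort.truth["cpgs"]
        region_truth = cohort.truth["regions"]
        for g in ("Suz12GT", "Suz12D", "Eednull"):
            lost_genes = set(region_truth.loc[
                (region_truth["genotype"] == g)
                & (region_truth["status"] == "lost"), "gene_id"])
            gaining = cpg_truth.loc[cpg_truth[f"gains_{g}"]]
            assert set(gaining["region_gene"]) <= lost_genes


class TestExpression:
    def _expr_setup(self, **kw):
        cfg = small_config(**kw)
        ann, cpgs, truth = simulate_genome(cfg)
        _, _, _, levels = simulate_chromatin(ann, truth, cfg)
        expr = simulate_expression(ann, truth, levels, cfg)
        return cfg, truth, levels, expr

    def test_all_fpkm_non_negative(self):
        _, _, _, expr = self._expr_setup()
        assert (expr.to_numpy() >= 0).all()

    def test_null_slope_gives_indistinguishable_change(self):
        from scipy import stats
        cfg, truth, levels, expr = self._expr_setup(
            expr_slope=0.0, n_genes=500, n_prc2_targets=250,
            genome_length=20_000_000, cpg_density=0.5,
            genotypes={"wt": 1.0, "null": 0.0})
        lfc = np.log2(expr["null_d0"] / expr["wt_d0"])
        is_t = truth["is_prc2_target"].to_numpy()
        ks = stats.ks_2samp(lfc[is_t], lfc[~is_t])
        assert ks.pvalue > 0.01

    def test_planted_slope_recovered_by_ols(self):
        cfg, truth, levels, expr = self._expr_setup(
            expr_slope=0.5, expr_noise_sd=0.1, n_genes=500,
            n_prc2_targets=250, genome_length=20_000_000, cpg_density=0.5,
            genotypes={"wt": 1.0, "null": 0.0})
        y = np.log2(expr["null_d0"] / expr["wt_d0"]).to_numpy()
        x = -(levels["null_d0"] - levels["wt_d0"]).to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)


class TestCohort:
    def test_identical_config_bit_identical_cohort(self, tiny_config, cohort):
        other = simulate_cohort(tiny_config)
        pd.testing.assert_frame_equal(other.annotation, cohort.annotation)
        pd.testing.assert_frame_equal(other.expression, cohort.expression)
        for key in cohort.read_sets:
            pd.testing.assert_frame_equal(other.read_sets[key],
                                          cohort.read_sets[key])
        for key in cohort.methylation:
            pd.testing.assert_frame_equal(other.methylation[key].data,
                                          cohort.methylation[key].data)

    def test_adding_a_genotype_preserves_existing_samples(self, tiny_config):
        import dataclasses
        cfg2 = dataclasses.replace(
            tiny_config,
            genotypes={**tiny_config.genotypes, "extra": 0.7})
        bigger = simulate_cohort(cfg2)
        base = simulate_cohort(tiny_config)
        pd.testing.assert_frame_equal(
            bigger.methylation[("wt", "d0")].data,
            base.methylation[("wt", "d0")].data)
        pd.testing.assert_frame_equal(
            bigger.read_sets[("Suz12GT", "d5", "k27")],
            base.read_sets[("Suz12GT", "d5", "k27")])
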