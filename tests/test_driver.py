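"""Replicate orchestration, power estimation, the gene-based scan, genomic
control and plot-data export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from granvil.driver import (
    CHI2_1_MEDIAN, ScanResult, SimulationScenario, estimate_power,
    export_plots_data, genomic_control, run_replicate, run_scan,
    scaled_scenario,
)


def _tiny_scenario(**kw):
    base = dict(n_hap=1000, n_individuals=150, length_bp=120_000,
                gene_length=30_000, r_panel=40, n_gwas=24, replicates=2,
                seed=3)
    base.update(kw)
    return scaled_scenario(**base)


class TestRunReplicate:
    def test_fixed_master_seed_reproducible(self):
        sc = _tiny_scenario()
        a = run_replicate(sc, 0)
        b = run_replicate(sc, 0)
        assert a.p_values == pytest.approx(b.p_values, nan_ok=True)
        assert a.counts == b.counts

    def test_replicates_differ(self):
        sc = _tiny_scenario()
        a = run_replicate(sc, 0)
        b = run_replicate(sc, 1)
        assert a.counts != b.counts or a.p_values != b.p_values

    def test_count_categories_present_and_ordered(self):
        sc = _tiny_scenario()
        r = run_replicate(sc, 0)
        assert set(r.counts) == {"population", "sequenced", "panel_genotyped",
                                 "chip", "well_imputed"}
        assert r.counts["sequenced"] <= r.counts["population"]
        assert r.counts["panel_genotyped"] <= r.counts["sequenced"]

    def test_null_scenario_p_values_not_extreme(self):
        # no causal variants: SEQ p should look uniform-ish over replicates
        sc = _tiny_scenario(q_total=0.0, replicates=40, seed=10)
        ps = [run_replicate(sc, i).p_values["SEQ"] for i in range(40)]
        ps = np.array([p for p in ps if np.isfinite(p)])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestEstimatePower:
    def test_all_significant(self):
        tab = pd.DataFrame({f"p_{s}": [0.001] * 10
                            for s in ("SEQ", "GEN", "GWAS", "IMP")})
        pw = estimate_power(tab)
        assert (pw["power"] == 1.0).all()
        assert (pw["mc_se"] == 0.0).all()

    def test_missing_p_counts_as_non_rejection(self):
        tab = pd.DataFrame({f"p_{s}": [np.nan] * 8
                            for s in ("SEQ", "GEN", "GWAS", "IMP")})
        assert (estimate_power(tab)["power"] == 0.0).all()

    def test_mc_se_formula(self):
        tab = pd.DataFrame({f"p_{s}": [0.01] * 5 + [0.5] * 15
                            for s in ("SEQ", "GEN", "GWAS", "IMP")})
        pw = estimate_power(tab)
        assert pw.loc[0, "power"] == pytest.approx(0.25)
        assert pw.loc[0, "mc_se"] == pytest.approx(np.sqrt(0.25 * 0.75 / 20))


class TestGenomicControl:
    def test_null_median_statistic_gives_unity(self):
        assert genomic_control(np.full(11, CHI2_1_MEDIAN)) == pytest.approx(1.0)

    def test_chi2_sample_close_to_one(self):
        rng = np.random.default_rng(15)
        stats_ = rng.chisquare(1, size=10**5)
        assert genomic_control(stats_) == pytest.approx(1.0, rel=0.01)

    def test_linearity(self):
        rng = np.random.default_rng(16)
        s = rng.chisquare(1, size=1001)
        assert genomic_control(2 * s) == pytest.approx(2 * genomic_control(s))


def _write_scan_inputs(tmp_path, rng, n_genes=40, n_samples=300,
                       planted=None, trait="P"):
    """Hard-call GEN + SAMPLE + genes files; one gene per 1 kb block.
    ``planted`` names a gene index whose burden drives the phenotype."""
    gene_lines, gen_lines = [], []
    burdens = {}
    for g in range(n_genes):
        start, stop = g * 1000 + 1, g * 1000 + 999
        gene_lines.append(f"1 {start} {stop} GENE{g}")
        carriers = np.zeros(n_samples)
        for j in range(6):
            pos = start + 10 + j * 20
            freq = rng.uniform(0.002, 0.008)
            geno = rng.binomial(1, 2 * freq, size=n_samples)
            carriers += geno
            triples = np.zeros((n_samples, 3))
            triples[np.arange(n_samples), geno] = 1.0
            gen_lines.append(
                f"snp{g}_{j} rs{g}_{j} {pos} A G "
                + " ".join(f"{v:g}" for v in triples.ravel()))
        burdens[g] = carriers / 6.0
    y = rng.standard_normal(n_samples)
    if planted is not None:
        y = y + 14.0 * burdens[planted]
    pc = rng.standard_normal(n_samples)
    sample_lines = ["ID_1 pheno pc1", f"0 {trait} C"] + [
        f"ind{i} {y[i]:.6f} {pc[i]:.6f}" for i in range(n_samples)
    ]
    (tmp_path / "g.gen").write_text("\n".join(gen_lines) + "\n")
    (tmp_path / "s.sample").write_text("\n".join(sample_lines) + "\n")
    (tmp_path / "genes.txt").write_text("\n".join(gene_lines) + "\n")
    return tmp_path / "g.gen", tmp_path / "s.sample", tmp_path / "genes.txt"


class TestRunScan:
    def test_planted_gene_attains_minimum_p(self, tmp_path):
        rng = np.random.default_rng(31)
        gen, sample, genes = _write_scan_inputs(tmp_path, rng, planted=7)
        scan = run_scan(gen, sample, genes)
        ok = scan.results[scan.results["status"] == "ok"]
        assert ok.loc[ok["p_value"].idxmin(), "gene"] == "GENE7"

    def test_null_scan_calibration(self, tmp_path):
        rng = np.random.default_rng(32)
        gen, sample, genes = _write_scan_inputs(tmp_path, rng, n_genes=120)
        scan = run_scan(gen, sample, genes)
        assert 0.7 < scan.lambda_gc < 1.3
        ok = scan.results[scan.results["status"] == "ok"]
        assert stats.kstest(ok["p_value"], "uniform").pvalue > 0.01

    def test_scan_invariant_to_gene_file_order(self, tmp_path):
        rng = np.random.default_rng(33)
        gen, sample, genes = _write_scan_inputs(tmp_path, rng, n_genes=10)
        scan1 = run_scan(gen, sample, genes)
        lines = genes.read_text().strip().split("\n")
        genes2 = genes.parent / "genes_shuffled.txt"
        genes2.write_text("\n".join(lines[::-1]) + "\n")
        scan2 = run_scan(gen, sample, genes2)
        pd.testing.assert_frame_equal(scan1.results, scan2.results)

    def test_bonferroni_override_thirty_thousand_genes(self, tmp_path):
        rng = np.random.default_rng(34)
        gen, sample, genes = _write_scan_inputs(tmp_path, rng, n_genes=5)
        scan = run_scan(gen, sample, genes, bonferroni_n=30_000)
        assert scan.bonferroni_threshold == pytest.approx(1.7e-6, rel=0.03)

    def test_gene_without_rare_variants_gets_status_row(self, tmp_path):
        rng = np.random.default_rng(35)
        gen, sample, genes = _write_scan_inputs(tmp_path, rng, n_genes=4)
        with open(genes, "a") as fh:
            fh.write("1 900000 900999 EMPTY\n")
        scan = run_scan(gen, sample, genes)
        row = scan.results[scan.results["gene"] == "EMPTY"].iloc[0]
        assert row["status"] == "no_rare_variants"
        assert np.isnan(row["p_value"])

    def test_trait_and_covariate_column_selection(self, tmp_path):
        rng = np.random.default_rng(37)
        gen, sample, genes = _write_scan_inputs(tmp_path, rng, n_genes=3)
        scan = run_scan(gen, sample, genes, trait_type="quantitative",
                        covariate_columns=["pc1"])
        assert (scan.results["status"] == "ok").all()
        with pytest.raises(ValueError, match="trait type"):
            run_scan(gen, sample, genes, trait_type="binary")
        with pytest.raises(ValueError, match="covariate columns"):
            run_scan(gen, sample, genes, covariate_columns=["nope"])

    def test_conditional_dosage_reduces_driven_signal(self, tmp_path):
        rng = np.random.default_rng(36)
        gen, sample, genes = _write_scan_inputs(tmp_path, rng, n_genes=6,
                                                planted=2)
        scan = run_scan(gen, sample, genes)
        p_before = float(
            scan.results.set_index("gene").loc["GENE2", "p_value"])
        # condition on a dosage equal to the planted burden signal itself
        from granvil.io_formats import read_gen
        from granvil.io_formats import carrier_posterior
        recs = [r for r in read_gen(gen) if 2001 <= r.position <= 2999]
        dosage = np.clip(
            np.sum([carrier_posterior(r)[0] for r in recs], axis=0), 0, 2)
        scan2 = run_scan(gen, sample, genes, condition_dosage=dosage)
        p_after = float(
            scan2.results.set_index("gene").loc["GENE2", "p_value"])
        assert p_after > p_before


class TestPlotExport:
    def _scan(self):
        df = pd.DataFrame({
            "gene": ["A", "B"], "chr": ["1", "1"],
            "start": [1, 100], "stop": [11, 200],
            "n_variants": [2, 3], "mean_maf": [0.1, 0.2],
            "beta": [0.0, 1.0], "se": [1.0, 1.0],
            "or_per_allele": [np.nan, np.nan],
            "lrt_stat": [0.0, 2.0], "p_value": [0.5, 0.02],
            "status": ["ok", "ok"],
        })
        return ScanResult(results=df, lambda_gc=1.0,
                          bonferroni_threshold=0.025, significant=["B"])

    def test_midpoint_and_flags(self):
        manhattan, _ = export_plots_data(self._scan())
        assert manhattan.loc[manhattan["gene"] == "A", "midpoint"].item() == 6
        assert manhattan["significant"].tolist() == [False, True]

    def test_qq_expected_quantiles(self):
        _, qq = export_plots_data(self._scan())
        np.testing.assert_allclose(
            qq["expected_neglog10_p"],
            -np.log10((np.arange(1, 3) - 0.5) / 2))
        assert qq["observed_neglog10_p"].iloc[0] == pytest.approx(
            -np.log10(0.02))


class TestScenarioConfig:
    def test_roundtrip_from_config(self, tmp_path):
        cfg = tmp_path / "scenario.cfg"
        cfg.write_text(
            "delta 0.005\nQ 0.02\nlambda 0.05\nR 500\nepsilon 0.001\n"
            "kappa 0.01\nn_gwas 240\nn_individuals 2000\nreplicates 500\n"
            "seed 42\n"
        )
        sc = SimulationScenario.from_config(cfg)
        assert sc.delta == 0.005 and sc.q_total == 0.02
        assert sc.r_panel == 500 and sc.replicates == 500
        assert sc.epsilon == 0.001 and sc.kappa == 0.01

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("frobnicate 3\n")
        with pytest.raises(ValueError, match="frobnicate"):
            SimulationScenario.from_config(cfg)
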