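"""Orchestration: the four-strategy power study over simulated replicates,
and the genome-wide gene-based scan with genomic control, Bonferroni
thresholding, conditional analysis and plot-data export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import assay, impute, simpop
from .burden import collapse_burden, conditional_adjust, test_burden
from .io_formats import (
    GeneRegion, SampleTable, carrier_posterior, expected_maf, read_gen,
    read_genes, read_sample,
)

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(sps.chi2.ppf(0.5, df=1))

STRATEGIES = ("SEQ", "GEN", "GWAS", "IMP")
COUNT_CATEGORIES = ("population", "sequenced", "panel_genotyped", "chip",
                    "well_imputed")


@dataclass
class SimulationScenario:
    """One cell of the power study design."""

    delta: float = 0.01       # maximum MAF of any causal variant
    q_total: float = 0.05     # total causal MAF target Q
    lam: float = 0.05         # causal contribution to trait variance
    r_panel: int = 120        # reference panel individuals R
    epsilon: float = 0.0      # per-allele base-call error
    kappa: float = 0.0        # per-genotype missingness
    n_gwas: int = 240         # chip variants in the window
    n_individuals: int = 2000
    n_hap: int = 40_000
    length_bp: int = 1_050_000
    gene_length: int = 50_000
    mu: float = 1e-8
    rec: float = 1e-8
    ne: int = 10_000
    replicates: int = 500
    seed: int = 1
    alpha: float = 0.05
    maf_threshold: float = 0.01
    info_threshold: float = 0.4
    ascertainment: str = "maf_weighted"  # or "uniform"

    @classmethod
    def from_config(cls, path) -> "SimulationScenario":
        """Key-value config file: one ``key = value`` or ``key value`` pair
        per line; '#' starts a comment.  Accepts the aliases Q, lambda, R."""
        aliases = {"q": "q_total", "lambda": "lam", "r": "r_panel"}
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                parts = line.replace("=", " ").split()
                key = aliases.get(parts[0].lower(), parts[0].lower())
                if key not in valid:
                    raise ValueError(f"unknown scenario key {parts[0]!r}")
                if valid[key] in ("str", str):
                    kwargs[key] = parts[1]
                else:
                    caster = int if valid[key] in ("int", int) else float
                    kwargs[key] = caster(float(parts[1]))
        return cls(**kwargs)


def scaled_scenario(**overrides) -> SimulationScenario:
    """Desk-scale study conditions: a 210 kb window (50 kb gene, 80 kb
    buffers) in a population of 4,000 haplotypes, a cohort of 500
    individuals and a chip density matching the full-scale default
    (~230 variants/Mb -> 48 in the window).  Trait model and panel size
    default to the rarer-causal-variant model (delta = 0.5%, Q = 2%,
    lambda = 5%); override any field by keyword."""
    base = dict(
        delta=0.005, q_total=0.02, lam=0.05, r_panel=120,
        n_hap=4000, n_individuals=500, length_bp=210_000,
        gene_length=50_000, n_gwas=48, replicates=200, seed=1,
    )
    base.update(overrides)
    return SimulationScenario(**base)


@dataclass
class ReplicateResult:
    p_values: dict       # strategy -> p (NaN when no qualifying variants)
    counts: dict         # category -> rare-variant count


def _replicate_seeds(master_seed: int, rep_index: int, n: int = 12) -> np.ndarray:
    """Deterministic counter scheme: every strategy within a replicate shares
    the population, cohort and phenotype seeds."""
    ss = np.random.SeedSequence((master_seed, rep_index))
    return ss.generate_state(n) % (2**31 - 2) + 1


def _test_matrix(e_g, observed, maf, phenotype) -> float:
    """Collapse + quantitative-trait burden test; NaN when nothing qualifies."""
    if e_g.shape[1] == 0:
        return np.nan
    design = collapse_burden(e_g, observed, maf)
    if not np.any(design.weights > 0):
        return np.nan
    res = test_burden(design, phenotype, None, "quantitative")
    return res.p_value


def carrier_from_genotypes(G: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Expected carrier indicator from hard genotype calls (counts of allele
    1), orienting each variant to its observed minor allele."""
    n_obs = observed.sum(axis=0)
    alt = np.where(observed, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, alt / (2.0 * n_obs), 0.0)
    carrier_alt = G >= 1      # carries >= 1 copy of allele 1
    carrier_ref = G <= 1      # carries >= 1 copy of allele 0
    return np.where(freq <= 0.5, carrier_alt, carrier_ref).astype(float)


def carrier_from_triples(triples: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """E(G) = 1 - h from posterior triples over allele-1 counts, orienting
    each variant to the minor allele by expected frequency."""
    e = triples[..., 1] + 2.0 * triples[..., 2]
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0,
                        np.where(observed, e, 0.0).sum(axis=0) / (2.0 * n_obs),
                        0.0)
    h = np.where(freq <= 0.5, triples[..., 0], triples[..., 2])
    return np.clip(np.where(observed, 1.0 - h, 0.0), 0.0, 1.0)


def run_replicate(scenario: SimulationScenario, rep_index: int) -> ReplicateResult:
    """Execute one full replicate of the simulation study: population,
    causal selection, cohort and phenotype, reference panel, error and
    missingness injection, the four assay strategies, and the burden test
    on each.  Returns per-strategy p-values and rare-variant counts."""
    sc = scenario
    seeds = _replicate_seeds(sc.seed, rep_index)
    pop = simpop.generate_population(
        n_hap=sc.n_hap, length_bp=sc.length_bp, mu=sc.mu, rec=sc.rec,
        ne=sc.ne, gene_length=sc.gene_length, seed=int(seeds[0]),
    )
    causal = simpop.select_causal(pop, sc.delta, sc.q_total, int(seeds[1]))
    cohort_idx = simpop.sample_cohort_indices(pop, sc.n_individuals,
                                              int(seeds[2]))
    m = simpop.causal_allele_counts(pop, cohort_idx, causal)
    if len(causal.indices) and 0.0 < sc.lam < 1.0:
        p_carrier = simpop.carrier_probability(pop, causal)
        sigma2 = simpop.residual_variance(p_carrier, sc.lam)
    else:
        sigma2 = 1.0  # null model: phenotype independent of genotype
    y = simpop.simulate_phenotype(m, sigma2, int(seeds[3]))
    panel_idx = simpop.sample_reference(pop, cohort_idx, sc.r_panel,
                                        int(seeds[4]))

    # errors go into the panel first, then the cohort
    panel_hap = assay.inject_errors(pop.haplotypes[panel_idx], sc.epsilon,
                                    int(seeds[5]))
    cohort_hap = assay.inject_errors(pop.haplotypes[cohort_idx], sc.epsilon,
                                     int(seeds[6]))
    n_ind = sc.n_individuals
    gene_cols = np.flatnonzero(pop.gene_mask)
    G_gene = cohort_hap[:, gene_cols].reshape(n_ind, 2, -1).sum(axis=1)

    counts = {"population": int((pop.q[gene_cols] < sc.maf_threshold).sum())}
    p_values = {}

    # SEQ: re-sequencing, no missingness
    obs_all = np.ones_like(G_gene, dtype=bool)
    _, G_seq, maf_seq = assay.strategy_seq(G_gene, obs_all, sc.maf_threshold)
    obs_seq = np.ones_like(G_seq, dtype=bool)
    counts["sequenced"] = G_seq.shape[1]
    p_values["SEQ"] = _test_matrix(
        carrier_from_genotypes(G_seq, obs_seq), obs_seq, maf_seq, y)

    # GEN: direct genotyping of panel variants, missingness kappa
    obs_gen_all = assay.inject_missing(G_gene.shape, sc.kappa, int(seeds[7]))
    keep_gen, G_gen, maf_gen = assay.strategy_gen(
        G_gene, obs_gen_all, panel_hap[:, gene_cols], sc.maf_threshold)
    obs_gen = obs_gen_all[:, keep_gen]
    counts["panel_genotyped"] = G_gen.shape[1]
    p_values["GEN"] = _test_matrix(
        carrier_from_genotypes(G_gen, obs_gen), obs_gen, maf_gen, y)

    # GWAS: chip variants only, missingness kappa
    chip = assay.chip_ascertain(pop, min(sc.n_gwas, pop.n_variants),
                                int(seeds[8]), ascertainment=sc.ascertainment)
    G_chip = cohort_hap[:, chip.variant_indices].reshape(n_ind, 2, -1).sum(axis=1)
    obs_chip = assay.inject_missing(G_chip.shape, sc.kappa, int(seeds[9]))
    chip_keep, G_gwas, maf_gwas = assay.strategy_gwas(
        chip, pop, G_chip, obs_chip, sc.maf_threshold)
    in_gene_chip = np.isin(chip.variant_indices,
                           gene_cols[pop.q[gene_cols] < sc.maf_threshold])
    counts["chip"] = int(in_gene_chip.sum())
    obs_gwas = obs_chip[:, np.isin(chip.variant_indices, chip_keep)]
    p_values["GWAS"] = _test_matrix(
        carrier_from_genotypes(G_gwas, obs_gwas), obs_gwas, maf_gwas, y)

    # IMP: chip scaffold + imputation up to the panel
    triples, obs_imp, maf_imp, info = _impute_gene(
        pop, cohort_hap, panel_hap, chip, G_chip, obs_chip, sc)
    keep_imp = impute.filter_imputed(maf_imp, info, sc.maf_threshold,
                                     sc.info_threshold)
    counts["well_imputed"] = len(keep_imp)
    if len(keep_imp):
        e_g = carrier_from_triples(triples[:, keep_imp], obs_imp[:, keep_imp])
        p_values["IMP"] = _test_matrix(e_g, obs_imp[:, keep_imp],
                                       maf_imp[keep_imp], y)
    else:
        p_values["IMP"] = np.nan

    return ReplicateResult(p_values=p_values, counts=counts)


def _impute_gene(pop, cohort_hap, panel_hap, chip, G_chip, obs_chip, sc):
    """Posterior triples for gene variants under the imputation strategy:
    panel gene sites imputed by the Li-Stephens HMM from the chip scaffold;
    typed chip sites in the gene overridden with their observed hard calls."""
    n_ind = cohort_hap.shape[0] // 2
    f_panel = panel_hap.mean(axis=0) if panel_hap.size else np.zeros(pop.n_variants)
    panel_cols = np.flatnonzero((f_panel > 0.0) & (f_panel < 1.0))
    gene_cols = np.flatnonzero(pop.gene_mask)
    gene_panel_cols = np.intersect1d(panel_cols, gene_cols)
    chip_gene_cols = np.intersect1d(chip.variant_indices, gene_cols)
    out_gene_cols = np.union1d(gene_panel_cols, chip_gene_cols)

    triples = np.zeros((n_ind, len(out_gene_cols), 3))
    observed = np.zeros((n_ind, len(out_gene_cols)), dtype=bool)

    if len(gene_panel_cols) and len(panel_cols):
        scaffold_cols = np.intersect1d(chip.variant_indices, panel_cols)
        sc_idx = np.searchsorted(panel_cols, scaffold_cols)
        params = impute.LSParams.from_panel(
            panel_hap.shape[0], pop.positions[panel_cols], ne=sc.ne, rec=sc.rec)
        # a kappa-masked genotype hides both of the individual's haplotypes
        chip_pos = np.searchsorted(chip.variant_indices, scaffold_cols)
        hap_obs = np.repeat(obs_chip[:, chip_pos], 2, axis=0)
        targets = cohort_hap[:, scaffold_cols]
        out_idx = np.searchsorted(panel_cols, gene_panel_cols)
        dosage = impute.ls_posteriors_batch(
            panel_hap[:, panel_cols], params, targets, hap_obs,
            sc_idx, out_idx)
        a, b = dosage[0::2], dosage[1::2]
        tri = impute.genotype_posteriors(a, b)
        pos_in_out = np.searchsorted(out_gene_cols, gene_panel_cols)
        triples[:, pos_in_out] = tri
        observed[:, pos_in_out] = True

    # typed chip variants in the gene: hard calls where observed
    if len(chip_gene_cols):
        chip_pos = np.searchsorted(chip.variant_indices, chip_gene_cols)
        pos_in_out = np.searchsorted(out_gene_cols, chip_gene_cols)
        g = G_chip[:, chip_pos]
        obs_g = obs_chip[:, chip_pos]
        hard = np.zeros(g.shape + (3,))
        hard[np.arange(g.shape[0])[:, None], np.arange(g.shape[1])[None, :],
             g.astype(int)] = 1.0
        upd = obs_g
        ti = triples[:, pos_in_out]
        ti[upd] = hard[upd]
        triples[:, pos_in_out] = ti
        ob = observed[:, pos_in_out]
        observed[:, pos_in_out] = ob | obs_g

    e = triples[..., 1] + 2.0 * triples[..., 2]
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0,
                        np.where(observed, e, 0.0).sum(axis=0) / (2.0 * n_obs),
                        0.0)
    maf = np.minimum(freq, 1.0 - freq)
    info = np.array([
        impute.info_score(triples[:, j], observed[:, j]) if n_obs[j] else 0.0
        for j in range(len(out_gene_cols))
    ])
    return triples, observed, maf, info


def run_study(scenario: SimulationScenario) -> pd.DataFrame:
    """Run all replicates of a scenario; one row per replicate with the four
    p-values and the five rare-variant counts."""
    rows = []
    for rep in range(scenario.replicates):
        res = run_replicate(scenario, rep)
        row = {f"p_{s}": res.p_values[s] for s in STRATEGIES}
        row.update(res.counts)
        rows.append(row)
        logger.debug("replicate %d: %s", rep, row)
    return pd.DataFrame(rows)


def estimate_power(replicate_table: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Power per strategy: the fraction of replicates with p < alpha.  A
    missing p (no qualifying variants) counts as a non-rejection.  Includes
    the Monte-Carlo standard error and mean rare-variant counts."""
    n = len(replicate_table)
    if n == 0:
        raise ValueError("no replicates")
    rows = []
    for s in STRATEGIES:
        p = replicate_table[f"p_{s}"]
        power = float((p < alpha).sum()) / n
        rows.append({
            "strategy": s,
            "power": power,
            "mc_se": float(np.sqrt(power * (1.0 - power) / n)),
            "replicates": n,
        })
    out = pd.DataFrame(rows)
    for cat in COUNT_CATEGORIES:
        if cat in replicate_table:
            out[f"mean_n_{cat}"] = float(replicate_table[cat].mean())
    return out


@dataclass
class ScanResult:
    results: pd.DataFrame
    lambda_gc: float
    bonferroni_threshold: float
    significant: list = field(default_factory=list)


def genomic_control(lrt_stats: np.ndarray) -> float:
    """Genomic-control inflation factor: median observed statistic over the
    null chi-square(1) median (0.4549).  Reported as a diagnostic; no
    correction is applied."""
    stats_arr = np.asarray(lrt_stats, dtype=float)
    stats_arr = stats_arr[np.isfinite(stats_arr)]
    if stats_arr.size == 0:
        raise ValueError("no finite statistics")
    return float(np.median(stats_arr) / CHI2_1_MEDIAN)


def run_scan(
    gen_path,
    sample_path,
    genes_path,
    maf_threshold: float = 0.01,
    info_threshold: float = 0.4,
    condition_dosage: np.ndarray | None = None,
    bonferroni_n: int | None = None,
    alpha: float = 0.05,
    trait_type: str | None = None,
    covariate_columns: list[str] | None = None,
) -> ScanResult:
    """Gene-based burden scan over a GEN/SAMPLE/gene-boundary input set.

    Per gene: variants inside the boundary passing the MAF and info filters
    are collapsed and tested with the sample table's covariates (plus the
    conditioning SNP dosage when given).  Genes with no qualifying variant
    get a status row.  The inflation factor and the Bonferroni threshold
    (alpha over the number of genes tested, or over ``bonferroni_n``) are
    attached.
    """
    records = read_gen(gen_path)
    table = read_sample(sample_path)
    genes = read_genes(genes_path)
    if not genes:
        raise ValueError("no genes to test")
    if records and records[0].n_samples != table.n_samples:
        raise ValueError("GEN and SAMPLE files disagree on sample count")
    if trait_type is not None and trait_type != table.trait_type:
        raise ValueError(
            f"requested trait type {trait_type!r} but the SAMPLE file "
            f"declares {table.trait_type!r}")
    genes = sorted(genes, key=lambda g: (g.chromosome, g.start))
    covariates = table.covariates
    if covariate_columns is not None:
        missing = set(covariate_columns) - set(table.covariate_names)
        if missing:
            raise ValueError(f"unknown covariate columns: {sorted(missing)}")
        idx = [table.covariate_names.index(c) for c in covariate_columns]
        covariates = table.covariates[:, idx]
    rows = []
    for gene in genes:
        rows.append(_scan_gene(gene, records, table, covariates,
                               maf_threshold, info_threshold,
                               condition_dosage))
    df = pd.DataFrame(rows)
    tested = df[df["status"] == "ok"]
    lam_gc = genomic_control(tested["lrt_stat"]) if len(tested) else np.nan
    n_for_bonf = bonferroni_n if bonferroni_n else len(tested)
    threshold = alpha / max(n_for_bonf, 1)
    significant = list(tested.loc[tested["p_value"] < threshold, "gene"])
    return ScanResult(results=df, lambda_gc=lam_gc,
                      bonferroni_threshold=threshold, significant=significant)


def _scan_gene(gene: GeneRegion, records, table: SampleTable, covariates,
               maf_threshold, info_threshold, condition_dosage):
    base = {"gene": gene.gene_id, "chr": gene.chromosome,
            "start": gene.start, "stop": gene.stop}
    e_list, obs_list, maf_list = [], [], []
    for rec in records:
        if not gene.contains(rec.position):
            continue
        e_g, obs, poly = carrier_posterior(rec)
        if not poly:
            continue
        maf = expected_maf(rec)
        info = impute.info_score(rec.prob_triples, ~rec.missing)
        if maf >= maf_threshold or info < info_threshold:
            continue
        e_list.append(e_g)
        obs_list.append(obs)
        maf_list.append(maf)
    if not e_list:
        return {**base, "n_variants": 0, "mean_maf": np.nan, "beta": np.nan,
                "se": np.nan, "or_per_allele": np.nan, "lrt_stat": np.nan,
                "p_value": np.nan, "status": "no_rare_variants"}
    e_g = np.column_stack(e_list)
    obs = np.column_stack(obs_list)
    design = collapse_burden(e_g, obs, np.array(maf_list))
    weights = design.weights
    cov = covariates
    if condition_dosage is not None:
        cov, weights = conditional_adjust(covariates, condition_dosage,
                                          weights)
        design.weights = weights
    res = test_burden(design, table.phenotype, cov, table.trait_type,
                      gene_id=gene.gene_id)
    return {**base, "n_variants": res.n_variants, "mean_maf": res.mean_maf,
            "beta": res.beta, "se": res.se,
            "or_per_allele": res.or_per_allele, "lrt_stat": res.lrt_stat,
            "p_value": res.p_value, "status": res.status}


def export_plots_data(scan: ScanResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Manhattan table (gene midpoint, -log10 p, significance flag) and QQ
    table (expected vs observed -log10 p for the ranked tested genes)."""
    df = scan.results
    tested = df[df["status"] == "ok"].copy()
    manhattan = pd.DataFrame({
        "gene": tested["gene"],
        "chr": tested["chr"],
        "midpoint": (tested["start"] + tested["stop"]) // 2,
        "neglog10_p": -np.log10(tested["p_value"]),
        "significant": tested["p_value"] < scan.bonferroni_threshold,
    })
    p_sorted = np.sort(tested["p_value"].to_numpy())
    n = len(p_sorted)
    qq = pd.DataFrame({
        "expected_neglog10_p": -np.log10((np.arange(1, n + 1) - 0.5) / n),
        "observed_neglog10_p": -np.log10(p_sorted),
    })
    return manhattan, qq
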