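"""The four strategies for assaying rare variation in the gene, plus the
base-call error and missingness models.

Strategies produce (individuals x variants) genotype data for the burden
test: SEQ re-sequences the cohort (all gene variants, cohort MAF < 1%); GEN
genotypes the cohort at rare gene variants segregating in a reference panel;
GWAS genotypes only chip variants, ascertained with a strong bias toward
common alleles; IMP supplements the chip scaffold with imputation (module
``impute``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simpop import HaplotypePopulation

RARE_MAF = 0.01


@dataclass
class ChipDesign:
    """Variants selected to stand in for a GWAS genotyping chip."""

    variant_indices: np.ndarray  # into the population, full region
    n_gwas: int


def cohort_genotypes(
    pop: HaplotypePopulation, cohort_indices: np.ndarray,
    variant_idx: np.ndarray,
) -> np.ndarray:
    """Hard diploid genotype calls (minor-allele counts 0/1/2) for the cohort
    at the given variants, pairing consecutive haplotypes."""
    M = pop.minor_haplotypes(variant_idx)[cohort_indices]
    n_ind = len(cohort_indices) // 2
    return M.reshape(n_ind, 2, -1).sum(axis=1)


def _genotype_maf(G: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Folded MAF per variant from observed genotype calls."""
    n_obs = observed.sum(axis=0)
    alt = np.where(observed, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_obs > 0, alt / (2.0 * n_obs), 0.0)
    return np.minimum(f, 1.0 - f)


def rare_filter(G: np.ndarray, observed: np.ndarray,
                maf_threshold: float = RARE_MAF) -> tuple[np.ndarray, np.ndarray]:
    """Indices of polymorphic variants with cohort MAF strictly below the
    threshold, and their MAFs."""
    maf = _genotype_maf(G, observed)
    keep = (maf > 0.0) & (maf < maf_threshold)
    return np.flatnonzero(keep), maf[keep]


def strategy_seq(
    gene_genotypes: np.ndarray, observed: np.ndarray,
    maf_threshold: float = RARE_MAF,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re-sequencing: every gene variant with cohort MAF < threshold.

    Returns (columns kept, genotype submatrix, MAFs); genotypes are the
    observed (possibly error-perturbed) cohort calls.
    """
    keep, maf = rare_filter(gene_genotypes, observed, maf_threshold)
    return keep, gene_genotypes[:, keep], maf


def strategy_gen(
    gene_genotypes: np.ndarray, observed: np.ndarray,
    panel_gene_haplotypes: np.ndarray,
    maf_threshold: float = RARE_MAF,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Panel genotyping: rare gene variants that are polymorphic among the
    reference panel's haplotypes ("present in the reference panel")."""
    if panel_gene_haplotypes.size == 0:
        return np.array([], dtype=int), gene_genotypes[:, :0], np.array([])
    f = panel_gene_haplotypes.mean(axis=0)
    in_panel = (f > 0.0) & (f < 1.0)
    keep, maf = rare_filter(gene_genotypes, observed, maf_threshold)
    keep_mask = in_panel[keep]
    return keep[keep_mask], gene_genotypes[:, keep[keep_mask]], maf[keep_mask]


def chip_ascertain(
    pop: HaplotypePopulation, n_gwas: int, seed: int,
    ascertainment: str = "maf_weighted",
    weights: np.ndarray | None = None,
) -> ChipDesign:
    """Select ``n_gwas`` chip variants from the full region, without
    replacement, with ascertainment probability proportional to
    q_j (1 - q_j) (default).

    The neutral folded site-frequency spectrum has density proportional to
    1/q + 1/(1-q); weighting draws by q(1-q) exactly cancels it, so the
    selected variants have an approximately uniform MAF distribution — the
    hallmark of GWAS chip content, which is strongly biased toward common
    alleles.  Pass ``ascertainment="uniform"`` or explicit ``weights`` to
    override.
    """
    if n_gwas > pop.n_variants:
        raise ValueError("n_gwas exceeds the number of variants in the window")
    if n_gwas == 0:
        return ChipDesign(variant_indices=np.array([], dtype=int), n_gwas=0)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    elif ascertainment == "maf_weighted":
        w = (pop.q * (1.0 - pop.q)).astype(float)
    elif ascertainment == "uniform":
        w = np.ones(pop.n_variants)
    else:
        raise ValueError(f"unknown ascertainment {ascertainment!r}")
    rng = np.random.default_rng(seed)
    # sequential weighted draw without replacement (Efraimidis-Spirakis keys)
    keys = rng.exponential(size=pop.n_variants) / np.maximum(w, 1e-300)
    keys[w <= 0] = np.inf
    chosen = np.argsort(keys)[:n_gwas]
    return ChipDesign(variant_indices=np.sort(chosen), n_gwas=n_gwas)


def strategy_gwas(
    chip: ChipDesign, pop: HaplotypePopulation,
    chip_genotypes: np.ndarray, observed: np.ndarray,
    maf_threshold: float = RARE_MAF,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chip-only: chip variants inside the gene with cohort MAF < threshold.
    Routinely empty — downstream treats that as a non-rejection."""
    lo, hi = pop.gene_interval
    pos = pop.positions[chip.variant_indices]
    in_gene = np.flatnonzero((pos >= lo) & (pos <= hi))
    G = chip_genotypes[:, in_gene]
    obs = observed[:, in_gene]
    keep, maf = rare_filter(G, obs, maf_threshold)
    return chip.variant_indices[in_gene[keep]], G[:, keep], maf


def inject_errors(calls: np.ndarray, epsilon: float, seed: int) -> np.ndarray:
    """Flip each binary allele call independently with probability epsilon
    (per-allele base-call error; a hom-ref genotype is miscalled with
    probability ~ 2 * epsilon)."""
    if epsilon == 0.0:
        return calls.copy()
    rng = np.random.default_rng(seed)
    flips = rng.random(calls.shape) < epsilon
    return np.where(flips, 1 - calls, calls).astype(calls.dtype)


def inject_missing(
    shape: tuple[int, ...], kappa: float, seed: int
) -> np.ndarray:
    """Observation mask with each genotype dropped independently with
    probability kappa.  Applied to the genotyped strategies (panel, chip,
    imputation scaffold), never to re-sequencing."""
    if kappa == 0.0:
        return np.ones(shape, dtype=bool)
    rng = np.random.default_rng(seed)
    return rng.random(shape) >= kappa
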