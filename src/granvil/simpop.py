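"""Coalescent haplotype populations, causal-variant selection and the
quantitative-trait model for the power study.

The default population is 40,000 haplotypes over a 1,050 kb region (a central
50 kb gene flanked by 500 kb imputation buffers) simulated under the neutral
coalescent with recombination: mutation rate 1e-8 per bp per generation,
uniform recombination 1 cM/Mb, effective population size Ne = 10,000.

The trait model: an individual's expected phenotype is 1 if they carry at
least one minor allele at any causal variant (a carrier), 0 otherwise;
phenotypes are Gaussian about that mean with residual variance sigma^2 chosen
so that carrier status explains a fraction lambda of the total trait
variance:  sigma^2 = p(1-p)(1-lambda)/lambda  for carrier probability p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import msprime
import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_N_HAP = 40_000
DEFAULT_LENGTH = 1_050_000
DEFAULT_GENE_LENGTH = 50_000
DEFAULT_MU = 1e-8
DEFAULT_REC = 1e-8  # 1 cM/Mb
DEFAULT_NE = 10_000


@dataclass
class HaplotypePopulation:
    """Binary haplotype-by-variant matrix with positions and folded MAFs."""

    haplotypes: np.ndarray   # (H, V) int8, 0 = ancestral, 1 = derived
    positions: np.ndarray    # 1-based bp, strictly increasing
    gene_interval: tuple[int, int]  # 1-based inclusive
    q: np.ndarray            # folded population MAF per variant

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def gene_mask(self) -> np.ndarray:
        lo, hi = self.gene_interval
        return (self.positions >= lo) & (self.positions <= hi)

    def minor_haplotypes(self, variant_idx=slice(None)) -> np.ndarray:
        """Haplotype matrix recoded so 1 = minor allele."""
        H = self.haplotypes[:, variant_idx]
        freq = H.mean(axis=0)
        return np.where(freq > 0.5, 1 - H, H)


@dataclass
class CausalSet:
    """Variants (indices into the population) chosen to affect the trait."""

    indices: np.ndarray
    q: np.ndarray
    delta: float
    q_target: float
    q_achieved: float


@dataclass
class Cohort:
    """Analysis cohort: individuals as ordered pairs of haplotype indices."""

    hap_indices: np.ndarray  # (2 * n_individuals,) into the population
    m: np.ndarray            # minor-allele count over causal variants
    phenotype: np.ndarray

    @property
    def n_individuals(self) -> int:
        return len(self.hap_indices) // 2


def generate_population(
    n_hap: int = DEFAULT_N_HAP,
    length_bp: int = DEFAULT_LENGTH,
    mu: float = DEFAULT_MU,
    rec: float = DEFAULT_REC,
    ne: int = DEFAULT_NE,
    gene_length: int = DEFAULT_GENE_LENGTH,
    seed: int = 1,
    max_retries: int = 5,
) -> HaplotypePopulation:
    """Simulate a haplotype population under the neutral coalescent with
    recombination (Hudson model, infinite-sites mutations).

    Deterministic under a fixed seed.  If the gene interval contains no
    segregating site, the simulation is retried with an incremented seed.
    The gene is the central ``gene_length`` bp of the region.
    """
    if min(n_hap, length_bp, ne) <= 0 or mu < 0 or rec < 0:
        raise ValueError("population parameters must be positive")
    if n_hap % 2:
        raise ValueError("n_hap must be even")
    centre = length_bp // 2
    gene_interval = (centre - gene_length // 2 + 1, centre + gene_length // 2)
    for attempt in range(max_retries):
        # diploid samples keep the classic theta = 4 Ne mu timescale
        ts = msprime.sim_ancestry(
            samples=n_hap // 2, ploidy=2, sequence_length=length_bp,
            recombination_rate=rec, population_size=ne,
            random_seed=seed + attempt,
        )
        ts = msprime.sim_mutations(
            ts, rate=mu, random_seed=seed + attempt,
            discrete_genome=False,
        )
        if ts.num_sites == 0:
            if mu == 0:
                raise ValueError("no segregating sites (mutation rate is 0)")
            continue
        positions = np.floor(ts.tables.sites.position).astype(np.int64) + 1
        H = np.empty((ts.num_sites, n_hap), dtype=np.int8)
        for j, var in enumerate(ts.variants()):
            H[j] = var.genotypes
        # infinite-sites floats can collide after flooring to bp: keep first
        keep = np.concatenate([[True], np.diff(positions) > 0])
        positions, H = positions[keep], H[keep]
        freq = H.mean(axis=1)
        seg = (freq > 0) & (freq < 1)
        positions, H, freq = positions[seg], H[seg], freq[seg]
        in_gene = (positions >= gene_interval[0]) & (positions <= gene_interval[1])
        if not in_gene.any():
            logger.info("no segregating site in gene; retrying with seed %d",
                        seed + attempt + 1)
            continue
        return HaplotypePopulation(
            haplotypes=np.ascontiguousarray(H.T),
            positions=positions,
            gene_interval=gene_interval,
            q=np.minimum(freq, 1.0 - freq),
        )
    raise RuntimeError(
        f"no segregating site in the gene after {max_retries} attempts"
    )


def load_haplotypes(path, gene_interval: tuple[int, int]) -> HaplotypePopulation:
    """Read a pre-simulated haplotype matrix from the text format:
    header ``#positions p1 p2 ...`` then one 0/1 row per haplotype."""
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "#positions":
            raise ValueError(f"{path}: expected '#positions ...' header")
        positions = np.array(header[1:], dtype=np.int64)
        H = np.loadtxt(fh, dtype=np.int8, ndmin=2)
    if H.shape[1] != len(positions):
        raise ValueError(f"{path}: haplotype width != number of positions")
    if np.any(np.diff(positions) <= 0):
        raise ValueError(f"{path}: positions must be strictly increasing")
    freq = H.mean(axis=0)
    return HaplotypePopulation(
        haplotypes=H, positions=positions, gene_interval=gene_interval,
        q=np.minimum(freq, 1.0 - freq),
    )


def save_haplotypes(pop: HaplotypePopulation, path) -> None:
    with open(path, "w") as fh:
        fh.write("#positions " + " ".join(map(str, pop.positions)) + "\n")
        np.savetxt(fh, pop.haplotypes, fmt="%d")


def select_causal(
    pop: HaplotypePopulation, delta: float, q_total: float, seed: int
) -> CausalSet:
    """Draw causal variants uniformly at random, without replacement, from
    gene variants with MAF < delta, until the cumulative MAF first reaches
    the target Q.  Q = 0 yields an empty set."""
    gene_idx = np.flatnonzero(pop.gene_mask & (pop.q < delta))
    if q_total <= 0.0:
        return CausalSet(
            indices=np.array([], dtype=int), q=np.array([]),
            delta=delta, q_target=q_total, q_achieved=0.0,
        )
    if pop.q[gene_idx].sum() < q_total:
        raise ValueError(
            f"gene cannot support Q={q_total}: total eligible MAF "
            f"{pop.q[gene_idx].sum():.4f}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(gene_idx)
    cum = np.cumsum(pop.q[order])
    n_take = int(np.searchsorted(cum, q_total)) + 1
    chosen = order[:n_take]
    return CausalSet(
        indices=np.sort(chosen), q=pop.q[np.sort(chosen)],
        delta=delta, q_target=q_total, q_achieved=float(cum[n_take - 1]),
    )


def carrier_probability(pop: HaplotypePopulation, causal: CausalSet) -> float:
    """Empirical probability that a random individual carries >= 1 minor
    allele at any causal variant, from disjoint haplotype pairs.

    Computed over the H/2 disjoint pairs (0,1), (2,3), ... of the population
    matrix; this respects the linkage disequilibrium among causal variants,
    which the independence approximation 1 - prod_j (1 - q_j)^2 does not.
    """
    if len(causal.indices) == 0:
        return 0.0
    M = pop.minor_haplotypes(causal.indices)
    H = pop.n_haplotypes - (pop.n_haplotypes % 2)
    per_hap = M[:H].any(axis=1)
    pairs = per_hap.reshape(-1, 2).any(axis=1)
    return float(pairs.mean())


def carrier_probability_independent(q: np.ndarray) -> float:
    """Linkage-free approximation 1 - prod_j (1 - q_j)^2."""
    return float(1.0 - np.prod((1.0 - np.asarray(q)) ** 2))


def residual_variance(p_carrier: float, lam: float) -> float:
    """Residual trait variance sigma^2 = p(1-p)(1-lambda)/lambda.

    Carrier status (effect 1) has variance p(1-p); requiring it to explain a
    fraction lambda of the total variance p(1-p) + sigma^2 gives the formula.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie strictly in (0, 1)")
    if not 0.0 < p_carrier < 1.0:
        raise ValueError("carrier probability must lie strictly in (0, 1)")
    return p_carrier * (1.0 - p_carrier) * (1.0 - lam) / lam


def sample_cohort_indices(
    pop: HaplotypePopulation, n_individuals: int, seed: int
) -> np.ndarray:
    """Sample 2 * n_individuals haplotype indices without replacement and
    pair them consecutively into individuals."""
    if 2 * n_individuals > pop.n_haplotypes:
        raise ValueError("not enough haplotypes for the cohort")
    rng = np.random.default_rng(seed)
    return rng.choice(pop.n_haplotypes, size=2 * n_individuals, replace=False)


def sample_reference(
    pop: HaplotypePopulation, cohort_indices: np.ndarray, r_individuals: int,
    seed: int,
) -> np.ndarray:
    """Sample 2R panel haplotype indices from the population remainder
    (disjoint from the cohort).  R = 0 yields an empty panel."""
    if r_individuals == 0:
        return np.array([], dtype=int)
    remainder = np.setdiff1d(np.arange(pop.n_haplotypes), cohort_indices)
    if 2 * r_individuals > len(remainder):
        raise ValueError("not enough haplotypes left for the reference panel")
    rng = np.random.default_rng(seed)
    return rng.choice(remainder, size=2 * r_individuals, replace=False)


def causal_allele_counts(
    pop: HaplotypePopulation, cohort_indices: np.ndarray, causal: CausalSet
) -> np.ndarray:
    """m_i: minor alleles carried by each individual over causal variants."""
    n_ind = len(cohort_indices) // 2
    if len(causal.indices) == 0:
        return np.zeros(n_ind, dtype=int)
    M = pop.minor_haplotypes(causal.indices)[cohort_indices]
    return M.reshape(n_ind, 2, -1).sum(axis=(1, 2))


def simulate_phenotype(m: np.ndarray, sigma2: float, seed: int) -> np.ndarray:
    """y_i ~ N(mu_i, sigma) with mu_i = 1 if m_i > 0 else 0."""
    if sigma2 <= 0.0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    mu = (np.asarray(m) > 0).astype(float)
    return mu + np.sqrt(sigma2) * rng.standard_normal(len(mu))
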