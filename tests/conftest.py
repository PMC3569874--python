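import numpy as np
import pytest

from granvil.io_formats import GenotypeRecord
from granvil.simpop import generate_population


@pytest.fixture(scope="session")
def small_pop():
    """A 210 kb window (central 50 kb gene) in 2,000 haplotypes."""
    return generate_population(n_hap=2000, length_bp=210_000, seed=42)


@pytest.fixture(scope="session")
def medium_pop():
    """A 4 Mb window in 2,000 haplotypes: a large variant pool for
    site-frequency-spectrum tests."""
    return generate_population(n_hap=2000, length_bp=4_000_000, seed=9)


def make_record(triples, snp_id="snp1", position=100, alleles=("A", "G")):
    return GenotypeRecord(
        snp_id=snp_id, rs_id=f"rs_{snp_id}", position=position,
        allele_a=alleles[0], allele_b=alleles[1],
        prob_triples=np.asarray(triples, dtype=float),
    )


def random_records(rng, n_variants, n_samples, positions=None):
    """GEN records with random (normalised) posterior triples and ~5%
    missing genotypes."""
    recs = []
    if positions is None:
        positions = np.sort(rng.choice(10**6, size=n_variants, replace=False)) + 1
    for j in range(n_variants):
        t = rng.dirichlet([8.0, 1.0, 0.3], size=n_samples)
        t[rng.random(n_samples) < 0.05] = 0.0
        recs.append(make_record(t, snp_id=f"snp{j}", position=int(positions[j])))
    return recs
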