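"""Readers and writers for the statistical-genetics text formats the tool touches.

The genotype dialect is the SNPTEST/IMPUTE "GEN" format: five leading columns
(snp_id, rs_id, position, allele A, allele B) followed by one posterior
probability triple (pAA, pAB, pBB) per sample.  The companion SAMPLE format
carries phenotypes and covariates with a two-row header (column names, then
type codes).  Gene boundaries come as whitespace-delimited
``chromosome start stop name`` rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: a probability triple must sum to 1 within this tolerance (or be all zero)
TRIPLE_SUM_TOL = 1e-3

#: SAMPLE-file column type codes: 0 identifier, D discrete covariate,
#: C continuous covariate, P continuous phenotype, B binary phenotype
SAMPLE_TYPE_CODES = frozenset("0DCPB")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass
class GenotypeRecord:
    """One variant row of a GEN file.

    ``prob_triples`` is an (n_samples, 3) array of genotype posterior
    probabilities ordered (pAA, pAB, pBB); a missing genotype is the
    all-zero triple and is flagged in ``missing``.
    """

    snp_id: str
    rs_id: str
    position: int
    allele_a: str
    allele_b: str
    prob_triples: np.ndarray
    missing: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.prob_triples = np.asarray(self.prob_triples, dtype=float)
        if self.prob_triples.ndim != 2 or self.prob_triples.shape[1] != 3:
            raise FormatError("prob_triples must be an (n_samples, 3) array")
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")
        sums = self.prob_triples.sum(axis=1)
        self.missing = sums == 0.0
        bad = ~self.missing & (np.abs(sums - 1.0) > TRIPLE_SUM_TOL)
        if bad.any():
            i = int(np.argmax(bad))
            raise FormatError(
                f"probability triple for sample {i} at {self.snp_id} sums to "
                f"{sums[i]:.4f} (tolerance {TRIPLE_SUM_TOL})"
            )

    @property
    def n_samples(self) -> int:
        return self.prob_triples.shape[0]


@dataclass
class GeneRegion:
    """A named functional unit; coordinates are 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > stop {self.stop}"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.stop

    @property
    def midpoint(self) -> int:
        return (self.start + self.stop) // 2


@dataclass
class SampleTable:
    """Phenotype and covariates per sample, from a SAMPLE file."""

    sample_id: np.ndarray
    phenotype: np.ndarray
    covariates: np.ndarray  # (n_samples, n_covariates), possibly 0 columns
    trait_type: str  # "quantitative" or "binary"
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = pd.Index(self.sample_id)
        if ids.has_duplicates:
            raise FormatError("duplicate sample ids in SAMPLE file")
        if self.trait_type not in ("quantitative", "binary"):
            raise FormatError(f"unknown trait type {self.trait_type!r}")
        if self.trait_type == "binary":
            obs = self.phenotype[~np.isnan(self.phenotype)]
            if not np.isin(obs, (0.0, 1.0)).all():
                raise FormatError("binary phenotype must be coded 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)


def read_gen(path) -> list[GenotypeRecord]:
    """Parse a GEN file into one :class:`GenotypeRecord` per variant.

    Raises :class:`FormatError`, naming the offending line, when a row's
    column count is not 5 + 3k or a probability triple violates the
    sum-to-one invariant.
    """
    records: list[GenotypeRecord] = []
    n_samples = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 8 or (len(fields) - 5) % 3 != 0:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 + 3k columns, got {len(fields)}"
                )
            k = (len(fields) - 5) // 3
            if n_samples is None:
                n_samples = k
            elif k != n_samples:
                raise FormatError(
                    f"{path}:{lineno}: {k} samples, expected {n_samples}"
                )
            try:
                probs = np.array(fields[5:], dtype=float).reshape(k, 3)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric probability") from exc
            try:
                rec = GenotypeRecord(
                    snp_id=fields[0],
                    rs_id=fields[1],
                    position=int(fields[2]),
                    allele_a=fields[3],
                    allele_b=fields[4],
                    prob_triples=probs,
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_gen(records: list[GenotypeRecord], path, decimals: int = 6) -> None:
    """Serialise records back to GEN; probabilities printed to ``decimals``."""
    with open(path, "w") as fh:
        for rec in records:
            lead = f"{rec.snp_id} {rec.rs_id} {rec.position} {rec.allele_a} {rec.allele_b}"
            probs = " ".join(
                f"{p:.{decimals}f}" for p in rec.prob_triples.ravel()
            )
            fh.write(f"{lead} {probs}\n")


def carrier_posterior(record: GenotypeRecord) -> tuple[np.ndarray, np.ndarray, bool]:
    """Orient a variant to its minor allele and return carrier expectations.

    Returns ``(e_g, observed, polymorphic)`` where ``e_g[i] = 1 - h_i`` is the
    expected indicator of carrying at least one minor allele (``h_i`` the
    posterior probability of the major-allele homozygote) and ``observed``
    masks samples with a non-missing triple.

    The minor allele is the one with expected cohort frequency <= 0.5
    (tie: allele B).  A variant whose expected frequency is exactly 0 or 1 is
    flagged non-polymorphic (``polymorphic=False``).
    """
    obs = ~record.missing
    if not obs.any():
        return np.zeros(record.n_samples), obs, False
    t = record.prob_triples[obs]
    # expected frequency of allele B from the posterior triples
    freq_b = (t[:, 1] + 2.0 * t[:, 2]).sum() / (2.0 * len(t))
    if freq_b <= 0.5:
        h = record.prob_triples[:, 0]  # AA is the major homozygote
        minor_freq = freq_b
    else:
        h = record.prob_triples[:, 2]
        minor_freq = 1.0 - freq_b
    e_g = np.where(obs, 1.0 - h, 0.0)
    e_g = np.clip(e_g, 0.0, 1.0)
    polymorphic = 0.0 < minor_freq and freq_b < 1.0
    return e_g, obs, polymorphic


def expected_maf(record: GenotypeRecord) -> float:
    """Expected minor allele frequency among non-missing samples (folded)."""
    obs = ~record.missing
    if not obs.any():
        return 0.0
    t = record.prob_triples[obs]
    freq_b = (t[:, 1] + 2.0 * t[:, 2]).sum() / (2.0 * len(t))
    return min(freq_b, 1.0 - freq_b)


def read_sample(path) -> SampleTable:
    """Parse a SNPTEST SAMPLE file (two header rows: names, then type codes).

    The phenotype column is the first column typed ``P`` (quantitative) or
    ``B`` (binary); every ``C``/``D`` column is treated as a covariate.
    Missing values are ``NA`` or ``-9``.
    """
    with open(path) as fh:
        names = fh.readline().split()
        codes = fh.readline().split()
    if len(names) != len(codes):
        raise FormatError(f"{path}: header rows have different lengths")
    for code in codes:
        if code not in SAMPLE_TYPE_CODES:
            raise FormatError(f"{path}: unknown column type code {code!r}")
    df = pd.read_csv(
        path, sep=r"\s+", skiprows=2, header=None, names=names,
        na_values=["NA", "-9"],
    )
    pheno_cols = [n for n, c in zip(names, codes) if c in ("P", "B")]
    if not pheno_cols:
        raise FormatError(f"{path}: no phenotype column (type P or B)")
    pheno_col = pheno_cols[0]
    trait_type = "binary" if codes[names.index(pheno_col)] == "B" else "quantitative"
    covar_names = [n for n, c in zip(names, codes) if c in ("C", "D")]
    covariates = df[covar_names].to_numpy(dtype=float) if covar_names else np.empty(
        (len(df), 0)
    )
    return SampleTable(
        sample_id=df[names[0]].astype(str).to_numpy(),
        phenotype=df[pheno_col].to_numpy(dtype=float),
        covariates=covariates,
        trait_type=trait_type,
        covariate_names=covar_names,
    )


def write_sample(table: SampleTable, path) -> None:
    code = "B" if table.trait_type == "binary" else "P"
    with open(path, "w") as fh:
        cols = ["ID_1", "pheno"] + list(table.covariate_names)
        fh.write(" ".join(cols) + "\n")
        fh.write(" ".join(["0", code] + ["C"] * len(table.covariate_names)) + "\n")
        for i in range(table.n_samples):
            y = table.phenotype[i]
            y_str = "NA" if np.isnan(y) else (
                f"{int(y)}" if table.trait_type == "binary" else f"{y:.6g}"
            )
            row = [str(table.sample_id[i]), y_str] + [
                f"{v:.6g}" for v in table.covariates[i]
            ]
            fh.write(" ".join(row) + "\n")


def read_genes(path) -> list[GeneRegion]:
    """Parse a gene-boundary file: ``chromosome start stop name`` per row."""
    genes: list[GeneRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 'chrom start stop name'"
                )
            genes.append(
                GeneRegion(
                    gene_id=fields[3],
                    chromosome=fields[0],
                    start=int(fields[1]),
                    stop=int(fields[2]),
                )
            )
    if not genes:
        logger.warning("gene file %s contains no regions", path)
    return genes


RESULT_COLUMNS = [
    "gene", "chr", "start", "stop", "n_variants", "mean_maf",
    "beta", "se", "or_per_allele", "lrt_stat", "p_value", "status",
]


def write_results(results: pd.DataFrame, path) -> None:
    """Write per-gene burden results as TSV with the canonical column order."""
    out = results.reindex(columns=RESULT_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
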