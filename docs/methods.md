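# Methods

## The burden model

`granvil` tests for association between a trait and an accumulation of minor
alleles at rare variants (MAF < 1% by default) inside a functional unit,
typically a gene.  For individual *i*, let *n_i* be the number of rare
variants successfully assayed and *x_i* the proportion of those at which the
individual carries at least one minor allele.  The trait is modelled in a
generalised linear framework,

    g(E[y_i]) = alpha + beta * x_i + gamma' c_i,

with identity link for quantitative traits and logit link for binary ones;
*c_i* are covariates (e.g. principal components of genotype data).  *beta*
is the expected phenotype difference between a carrier of a full complement
of minor alleles and a non-carrier, so *beta/N* is the per-minor-allele
effect and `exp(beta/N)` the per-allele odds ratio for binary traits.

Genotype uncertainty is handled through the posterior genotype
probabilities: the carriage indicator at variant *j* is replaced by its
expectation `E(G_ij) = 1 - h_ij`, where *h_ij* is the posterior probability
of the major-allele homozygote.  Hard calls are the special case
`E(G) in {0, 1}`.

Differential call rates are handled by weighting individual *i*'s
log-likelihood contribution by *w_i = n_i / N*, where *N* is the total
number of rare variants in the unit.  The normalisation by *N* makes the
weighted likelihood reduce **exactly** to the ordinary GLM likelihood when
data are complete (all *n_i = N*), which the test suite asserts to 1e-8
against closed-form least squares (gaussian) and statsmodels (binomial);
unscaled weights would inflate the deviance *N*-fold.  Individuals with
*n_i = 0* receive weight 0 and drop out of the likelihood, as do individuals
with a missing phenotype or covariate (listwise).

Association is assessed by analysis of deviance: the weighted likelihood is
maximised with *beta* free and with *beta = 0* (covariates stay in both),
and `LRT = 2 (l_alt - l_null)`, clipped at zero, is referred to a chi-square
distribution with 1 degree of freedom.

Numerical choices: the gaussian family is solved in one weighted
least-squares step with the residual variance profiled out
(`sigma^2 = sum w r^2 / sum w`); the binomial family by iteratively
reweighted least squares, converged when the relative log-likelihood change
falls below 1e-8 (at most 100 iterations).  Normal equations are solved via
the pseudo-inverse, so exact collinearity (e.g. a burden fully determined by
a conditioning SNP) degrades gracefully to a zero statistic instead of
failing.  Linear predictors exceeding 30 in absolute value flag possible
complete separation.  Constant covariate columns are dropped with a warning.
Minor-allele orientation is decided per variant from the expected allele
frequency in the sample (ties assign allele B minor); variants whose
expected frequency is exactly 0 or 1 are flagged non-polymorphic and
excluded.

Conditional analysis appends the expected minor-allele dosage (0–2) of a
named lead SNP to the covariates of both models; samples missing that
dosage get weight 0 for the gene.

## Genome-wide scan diagnostics

The scan orders genes by position, tests each, and reports

* the genomic-control inflation factor `lambda_GC = median(LRT) / 0.4549`
  (the chi-square(1) median), as a diagnostic only — no correction is
  applied to the p-values;
* a Bonferroni threshold `alpha / n_genes`, with the number of genes
  overridable (e.g. 30,000 genome-wide, giving p < 1.7e-6 at alpha = 0.05);
* Manhattan data (transcript midpoint `floor((start+stop)/2)` vs
  -log10 p) and QQ data (expected quantiles `-log10((i - 0.5)/n)`).

## The simulation study

The power study compares four strategies for assaying rare variation in a
50 kb gene, in an analysis cohort of 2,000 individuals:

1. **SEQ** — re-sequencing: every gene variant with cohort MAF < 1%.
2. **GEN** — direct genotyping of every rare gene variant segregating in a
   reference panel of *R* individuals.
3. **GWAS** — genotyping only variants on a GWAS chip (almost never rare).
4. **IMP** — the chip scaffold supplemented with imputation up to the panel,
   keeping variants with expected MAF < 1% and info score >= 0.4.

### Population and trait model

Haplotype populations (40,000 haplotypes over 1,050 kb by default: the
central 50 kb gene plus 500 kb buffers) are simulated with msprime under the
neutral Hudson coalescent with recombination — mutation 1e-8 /bp/gen,
recombination 1 cM/Mb, Ne = 10,000, infinite-sites mutations floored to
integer bp.  msprime's haploid samples use an Ne-generation coalescent
timescale, so the generator simulates n/2 diploids and takes their phased
haplotypes, preserving the classic `theta = 4 Ne mu`; the test suite checks
mean pairwise diversity against that expectation.

Causal variants are drawn uniformly at random, without replacement, from
gene variants with MAF below `delta`, until their cumulative MAF first
reaches the target `Q` (exact equality is generally unattainable, so the
realised total lies in `[Q, Q + delta)`).  An individual's expected trait is
1 if they carry at least one causal minor allele and 0 otherwise;
phenotypes are Gaussian with residual variance

    sigma^2 = p (1 - p) (1 - lambda) / lambda,

so that carrier status explains the fraction `lambda` of the trait
variance.  The carrier probability *p* is computed **empirically** from
disjoint haplotype pairs of the population matrix rather than from the
independence approximation `1 - prod (1 - q_j)^2`, because linkage
disequilibrium among causal variants breaks independence.  The formula is
validated by an empirical variance decomposition over 1e6 simulated
phenotypes (R^2 of the carrier indicator ~= lambda).

### Chip ascertainment

GWAS chips are strongly biased towards common alleles; their content has an
approximately uniform MAF distribution.  The chip stand-in draws `n_GWAS`
variants (default 240 per 1,050 kb, ~the Illumina 660W genome-wide density
of ~230 variants/Mb) from the full window, without replacement, with weight
`q(1-q)`.  Under the folded neutral site-frequency spectrum (density
proportional to `1/q + 1/(1-q)`) this weight cancels the spectrum exactly,
so the selected-MAF distribution is uniform in expectation; a plain `q`
weight would leave a residual `1 + q/(1-q)` tilt.  The weight function is
pluggable (`ascertainment="uniform"` or explicit weights).

### Error and missingness models

Base-call errors flip each allele call independently with probability
`epsilon` (so hom-ref genotypes are miscalled at ~`2 epsilon`); they are
injected into the reference panel first, then into the cohort, and apply to
every strategy.  Missingness masks each genotype independently with
probability `kappa` and applies to the genotyped strategies (GEN, GWAS and
the imputation scaffold) but not to re-sequencing.  Cohort MAF filters are
computed from the observed (post-error) calls.

### Imputation stand-in

Full imputation machinery (IMPUTEv2/BEAGLE-style MCMC over diplotypes) is
out of scope; imputation is a haploid Li–Stephens hidden Markov model run
per cohort haplotype.  Cohort haplotypes are treated as pre-phased — the
simulator knows the true phase, mirroring the pre-phasing workflow used
with real data.  With a panel of K haplotypes, the switch probability
between adjacent sites at distance *d* is `1 - exp(-4 Ne r d / K)` and the
emission mismatch probability is `theta~ / (2 (theta~ + K))` with
`theta~ = 1 / sum_{k<K} 1/k` (the K = 1 panel falls back to `theta~ = 1`).
Typed (chip) sites emit the observed allele; untyped sites emit nothing and
receive the copying-state-weighted panel allele as their posterior.  The
forward–backward pass is checked against a brute-force path-enumeration
oracle on toy panels.  Per-individual genotype posteriors combine the two
haplotype posteriors as `(p0, p1, p2) = ((1-a)(1-b), a(1-b)+b(1-a), ab)`;
typed chip variants inside the gene keep their observed hard calls.
Identical panel haplotypes are collapsed into one copying state with a
multiplicity weight — an exact reformulation — and the chain runs in
float32 with per-site rescaling; collapsed and uncollapsed chains agree to
~1e-4, which is far below any quantity of interest (power, info scores,
dosage errors).

Imputation quality is summarised by the IMPUTE-style info score: with
expected dosage `e_i = p1 + 2 p2`, second moment `f_i = p1 + 4 p2` and
estimated frequency `theta = sum e_i / 2N`,

    info = 1 - sum(f_i - e_i^2) / (2 N theta (1 - theta)),

clipped to [0, 1]; hard calls give exactly 1 and a monomorphic estimate
gives 0.  The retention filter keeps expected MAF < 1% (strict) and
info >= 0.4 (inclusive — the threshold is configurable).

### Power estimation

Power is the fraction of replicates with p < 0.05.  Replicates where a
strategy has no qualifying rare variant count as **non-rejections** — the
GWAS-chip strategy routinely has none, and treating them as missing would
bias its power upward.  A master seed expands deterministically into
per-replicate seeds, so all strategies within a replicate share the same
population, cohort, phenotypes and panel, and error-model comparisons run
on matched replicates.

### Desk-scale study conditions

The full-scale defaults (40,000 haplotypes, 1,050 kb, cohort 2,000,
R in {120, 500, 4000}, 500 replicates) are expensive; the test suite and
the bundled scaled scenario (`driver.scaled_scenario`) use a 210 kb window
(50 kb gene, 80 kb buffers), 4,000 haplotypes, a cohort of 500, 48 chip
variants (the same per-Mb density) and 200 replicates, with panels of
R = 120 and R = 600.  Under these conditions the strategy ordering
SEQ >= GEN >= GWAS and the improvement of imputation with panel size are
clearly resolved within Monte-Carlo error, which is what the qualitative
claims require.  The acceptance script's null-calibration run uses 4,000
haplotypes over the full 1,050 kb window with a cohort of 500 and 1,000
replicates.

## What the generator does and does not emulate

The simulator captures the allele-frequency spectrum, linkage
disequilibrium and rare-variant sharing structure of a neutrally evolving,
panmictic, constant-size population, and a single-direction trait model
(every causal variant increases the trait; all effects equal).
It does **not** model selection, demography or population stratification,
gain-vs-loss-of-function mixtures, genotyping-intensity artefacts,
reference-panel phasing error (the panel is perfectly phased by
construction), or ancestry mismatch between cohort and panel.  Passing
power and calibration tests therefore demonstrate correctness of the
machinery under the stated generative model, not performance on real
cohorts with structure or mismatched panels.

## Known limitations

* The burden collapse assumes unidirectional effects; bidirectional
  (gain/loss) architectures call for variance-component tests, which are
  out of scope here.
* The Li–Stephens stand-in makes no claim of numerical agreement with
  IMPUTEv2's info scores — only the formula above is implemented.
* GEN input carries no chromosome column; a scan matches variants to genes
  by position only, so multi-chromosome inputs must be supplied per
  chromosome (the SNPTEST convention).
* X-chromosome dosage models and MAF-dependent variant weighting are not
  implemented.
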