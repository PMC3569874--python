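"""Gene-based rare-variant burden test.

Rare variants in a functional unit are collapsed per individual into the
proportion x_i of successfully assayed rare variants at which the individual
carries at least one minor allele (expected carriage 1 - h_ij under genotype
uncertainty).  The phenotype is regressed on x_i in a generalised linear
model whose per-individual log-likelihood contribution is weighted by the
individual's call rate, w_i = n_i / N, and association is assessed by a
likelihood-ratio test on 1 degree of freedom.

beta is the expected phenotype increase for a full complement of minor
alleles; beta / N is the increase per rare minor allele, so for binary
traits exp(beta / N) is the odds ratio per minor allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MAX_ITER = 100
#: IRLS stops when the relative log-likelihood change falls below this
LL_RTOL = 1e-8
#: linear predictors beyond this magnitude indicate (quasi-)separation
ETA_SEPARATION = 30.0


@dataclass
class BurdenDesign:
    """Collapsed per-individual burden predictor for one functional unit."""

    x: np.ndarray        # carrier proportion in [0, 1]
    n_assayed: np.ndarray  # rare variants successfully assayed per individual
    n_variants: int      # N, total rare variants in the unit
    weights: np.ndarray = field(init=False)  # w_i = n_i / N
    mean_maf: float = 0.0  # mean cohort MAF of included variants (fraction)

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("design requires at least one rare variant")
        self.weights = self.n_assayed / float(self.n_variants)


@dataclass
class GLMFit:
    """A fitted weighted GLM (gaussian-identity or binomial-logit)."""

    family: str
    coefficients: np.ndarray  # [intercept, burden (if included), covariates...]
    log_likelihood: float
    converged: bool
    iterations: int
    includes_burden: bool
    scale: float = np.nan  # gaussian residual variance (MLE), NaN for binomial
    separated: bool = False


@dataclass
class BurdenResult:
    """Per-gene burden test output."""

    gene_id: str
    n_variants: int
    mean_maf: float  # percent
    beta: float
    se: float
    lrt_stat: float
    p_value: float
    or_per_allele: float = np.nan
    or_ci_low: float = np.nan
    or_ci_high: float = np.nan
    status: str = "ok"


def collapse_burden(
    e_g: np.ndarray,
    observed: np.ndarray,
    maf: np.ndarray | None = None,
) -> BurdenDesign:
    """Collapse an (individuals x variants) expected-carriage matrix.

    ``e_g[i, j]`` is the expected indicator E(G_ij) = 1 - h_ij that
    individual i carries a minor allele at rare variant j; ``observed`` masks
    successfully assayed genotypes.  Variants must already be filtered to the
    rare-MAF (and, for imputed data, info-score) thresholds.

    Raises ``ValueError`` when no variant qualifies; callers translate this
    into a ``no_rare_variants`` status row.
    """
    e_g = np.atleast_2d(np.asarray(e_g, dtype=float))
    observed = np.atleast_2d(np.asarray(observed, dtype=bool))
    n_ind, n_var = e_g.shape
    if n_var == 0:
        raise ValueError("no rare variants in the unit")
    n_i = observed.sum(axis=1)
    total = np.where(observed, e_g, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        x = np.where(n_i > 0, total / np.maximum(n_i, 1), 0.0)
    design = BurdenDesign(x=x, n_assayed=n_i.astype(float), n_variants=n_var)
    if maf is not None:
        design.mean_maf = float(np.mean(maf))
    return design


def _weighted_lstsq(X: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve the weighted least-squares normal equations via pinv (tolerates
    collinear columns, e.g. a burden fully determined by a conditioning SNP)."""
    sw = np.sqrt(w)
    return np.linalg.pinv(sw[:, None] * X) @ (sw * z)


def _gaussian_loglik(y, mu, w) -> tuple[float, float]:
    W = w.sum()
    rss = float(np.sum(w * (y - mu) ** 2))
    sigma2 = rss / W
    if sigma2 <= 0.0:
        sigma2 = np.finfo(float).tiny
    ll = -0.5 * W * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return ll, sigma2


def _binomial_loglik(y, p, w) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def fit_weighted_glm(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    weights: np.ndarray,
    family: str,
    include_burden: bool = True,
) -> GLMFit:
    """Maximise the weighted log-likelihood sum_i w_i log L_i by IRLS.

    ``include_burden=False`` fits the null model (beta constrained to 0);
    covariates are always included in both models.  Individuals with zero
    weight are excluded from the likelihood.  Constant covariate columns are
    dropped with a warning.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    cols = [np.ones_like(y)]
    if include_burden:
        cols.append(x)
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        for j in range(C.shape[1]):
            col = C[:, j]
            if np.ptp(col[w > 0]) == 0.0:
                logger.warning("dropping constant covariate column %d", j)
                continue
            cols.append(col)
    X = np.column_stack(cols)

    keep = w > 0
    Xk, yk, wk = X[keep], y[keep], w[keep]
    if len(yk) <= X.shape[1]:
        raise ValueError("fewer effective observations than parameters")

    if family == "gaussian":
        beta = _weighted_lstsq(Xk, yk, wk)
        mu = Xk @ beta
        ll, sigma2 = _gaussian_loglik(yk, mu, wk)
        return GLMFit(
            family=family, coefficients=beta, log_likelihood=ll,
            converged=True, iterations=1, includes_burden=include_burden,
            scale=sigma2,
        )

    # binomial-logit IRLS on the weighted likelihood
    beta = np.zeros(Xk.shape[1])
    ybar = np.clip(np.average(yk, weights=wk), 1e-6, 1.0 - 1e-6)
    beta[0] = np.log(ybar / (1.0 - ybar))
    ll_old = -np.inf
    converged = False
    separated = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = Xk @ beta
        separated = bool(np.max(np.abs(eta)) > ETA_SEPARATION)
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        ll = _binomial_loglik(yk, p, wk)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= LL_RTOL * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll
        v = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (yk - p) / v
        beta = _weighted_lstsq(Xk, z, wk * v)
    eta = Xk @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    ll = _binomial_loglik(yk, p, wk)
    if separated:
        logger.warning("possible complete separation (|eta| > %.0f)", ETA_SEPARATION)
    return GLMFit(
        family=family, coefficients=beta, log_likelihood=ll,
        converged=converged, iterations=it, includes_burden=include_burden,
        separated=separated,
    )


def burden_se(fit: GLMFit, x, y, covariates, weights) -> float:
    """Standard error of the burden coefficient from the observed information
    of the weighted likelihood at the fitted coefficients."""
    if not fit.includes_burden:
        raise ValueError("fit does not include the burden term")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    cols = [np.ones_like(y), x]
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        for j in range(C.shape[1]):
            if np.ptp(C[w > 0][:, j]) != 0.0:
                cols.append(C[:, j])
    X = np.column_stack(cols)
    keep = w > 0
    Xk, yk, wk = X[keep], y[keep], w[keep]
    eta = Xk @ fit.coefficients
    if fit.family == "gaussian":
        v = np.full_like(yk, 1.0 / fit.scale)
    else:
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        v = np.clip(p * (1.0 - p), 1e-10, None)
    info = (Xk * (wk * v)[:, None]).T @ Xk
    try:
        cov = np.linalg.pinv(info)
        return float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        return np.nan


def lrt(null_fit: GLMFit, alt_fit: GLMFit) -> tuple[float, float]:
    """Likelihood-ratio statistic 2(l_alt - l_null), clipped at 0, against
    chi-square with 1 df.  Returns (statistic, p); p is NaN when either fit
    failed to converge."""
    stat = max(0.0, 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood))
    if not (null_fit.converged and alt_fit.converged):
        return stat, np.nan
    return stat, float(stats.chi2.sf(stat, df=1))


def or_per_minor_allele(
    beta: float, se: float, n_variants: int
) -> tuple[float, tuple[float, float]]:
    """Odds ratio per rare minor allele, exp(beta / N), with 95% CI."""
    if n_variants < 1:
        raise ValueError("odds ratio per allele undefined for N = 0")
    or_ = float(np.exp(beta / n_variants))
    lo = float(np.exp((beta - 1.959963984540054 * se) / n_variants))
    hi = float(np.exp((beta + 1.959963984540054 * se) / n_variants))
    return or_, (min(lo, hi), max(lo, hi))


def conditional_adjust(
    covariates: np.ndarray | None,
    lead_snp_dosage: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Append a lead SNP's minor-allele dosage (in [0, 2]) to the covariate
    matrix for a conditional analysis.  Samples with missing dosage get
    weight 0 for this gene.  Returns (augmented_covariates, weights)."""
    d = np.asarray(lead_snp_dosage, dtype=float)
    if np.nanmax(d, initial=0.0) > 2.0 or np.nanmin(d, initial=0.0) < 0.0:
        raise ValueError("lead SNP dosage must lie in [0, 2]")
    w = np.asarray(weights, dtype=float).copy()
    miss = np.isnan(d)
    if miss.any():
        logger.warning("%d samples missing lead-SNP dosage: weight set to 0",
                       int(miss.sum()))
        w[miss] = 0.0
        d = np.where(miss, 0.0, d)
    if covariates is None or covariates.size == 0:
        aug = d[:, None]
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(d):
            C = C.T
        aug = np.column_stack([C, d])
    return aug, w


def test_burden(
    design: BurdenDesign,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    trait_type: str,
    gene_id: str = "",
) -> BurdenResult:
    """Run the full weighted-GLM likelihood-ratio burden test on a collapsed
    design.  Individuals with a missing phenotype or covariate are excluded
    listwise (weight 0)."""
    family = "binomial" if trait_type == "binary" else "gaussian"
    y = np.asarray(phenotype, dtype=float)
    w = design.weights.copy()
    bad = np.isnan(y)
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        bad |= np.isnan(C).any(axis=1)
    w[bad] = 0.0
    y = np.where(bad, 0.0, y)

    null_fit = fit_weighted_glm(design.x, y, covariates, w, family,
                                include_burden=False)
    alt_fit = fit_weighted_glm(design.x, y, covariates, w, family,
                               include_burden=True)
    stat, p = lrt(null_fit, alt_fit)
    beta = float(alt_fit.coefficients[1])
    se = burden_se(alt_fit, design.x, y, covariates, w)
    result = BurdenResult(
        gene_id=gene_id,
        n_variants=design.n_variants,
        mean_maf=design.mean_maf * 100.0,
        beta=beta,
        se=se,
        lrt_stat=stat,
        p_value=p,
        status="ok" if np.isfinite(p) else "not_converged",
    )
    if family == "binomial" and np.isfinite(se):
        or_, (lo, hi) = or_per_minor_allele(beta, se, design.n_variants)
        result.or_per_allele, result.or_ci_low, result.or_ci_high = or_, lo, hi
    return result
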