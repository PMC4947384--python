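"""Association and heterogeneity testing in a logistic modelling framework.

For variant j with additively coded dosages g, the association model is

    logit P(y=1) = alpha + beta * g + gamma' x

where x holds the axes of genetic variation (AGV) and any extra covariates.
A 1-df likelihood-ratio test compares the maximised log-likelihood against
the null beta = 0.

Heterogeneity of allelic effects between ancestry groups is tested by
extending the model with interactions between the variant and the first two
AGV, which separate the major ancestry groups:

    logit P(y=1) = alpha + beta * g + gamma' x + lambda1 * g x1 + lambda2 * g x2

and forming a 2-df likelihood-ratio test of lambda1 = lambda2 = 0.  A
variant whose effect differs along the ancestry axes (for example, a weaker
odds ratio in East Asian ancestry individuals) shows up as a nonzero
interaction with the corresponding axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, stats
from scipy.special import expit

from .geno_io import GenotypeMatrix, PhenoCovariates, ValidationError

GENOME_WIDE_P = 5e-8

# IRLS convergence: score sup-norm, relative log-likelihood change, iteration cap
SCORE_TOL = 1e-8
LL_TOL = 1e-10
MAX_ITER = 100


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


class DegeneratePhenotypeError(ValueError):
    """Phenotype has a single class."""


@dataclass
class FittedModel:
    params: np.ndarray
    cov: np.ndarray  # inverse observed information
    loglik: float
    converged: bool
    separation: bool = False
    n_iter: int = 0
    colnames: Optional[list] = None

    def se(self, j: int) -> float:
        return float(np.sqrt(self.cov[j, j]))


def _rank_check(X: np.ndarray, colnames) -> None:
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        names = colnames or [f"col{i}" for i in range(X.shape[1])]
        offending = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise CollinearityError(
            f"design matrix is rank deficient; offending columns: {offending}"
        )


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    colnames: Optional[list] = None,
    start: Optional[np.ndarray] = None,
    check_rank: bool = True,
) -> FittedModel:
    """Maximum-likelihood logistic regression by Newton-Raphson/IRLS.

    Converges when the score sup-norm falls below 1e-8 or the relative
    log-likelihood change below 1e-10, within 100 iterations; step-halving
    guards against overshooting.  Complete separation (the fit classifies
    every observation perfectly, so the likelihood has no maximiser) sets
    ``converged=False`` and the separation flag rather than raising;
    downstream tests then refuse to report a P value.  Quasi-separation of
    nuisance covariates — e.g. an all-control ancestry group pushed to
    fitted probability ~0 along an ancestry axis — is benign for
    likelihood-ratio testing: the log-likelihood plateaus at its supremum
    and the fit stops there.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be n x p with n matching y")
    if y.min() == y.max():
        raise DegeneratePhenotypeError("phenotype has a single class")
    if check_rank:
        _rank_check(X, colnames)

    n, p = X.shape
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    converged = False
    separation = False
    it = 0
    H = None
    for it in range(1, MAX_ITER + 1):
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            c, low = linalg.cho_factor(H)
            delta = linalg.cho_solve((c, low), score)
        except linalg.LinAlgError:
            raise CollinearityError(
                "singular information matrix (collinear design or degenerate fit)"
            ) from None
        # step-halving line search on the log-likelihood
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            eta_c = X @ cand
            ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        beta, eta = beta + step * delta, eta_c
        if abs(ll_c - ll) < LL_TOL * (abs(ll) + LL_TOL):
            ll = ll_c
            converged = True
            break
        ll = ll_c

    mu = expit(eta)
    # perfect classification: the likelihood has no maximiser (separation)
    if np.max(np.abs(y - mu)) < 1e-6:
        separation = True
        converged = False

    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = linalg.inv(H)
    except linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return FittedModel(
        params=beta,
        cov=cov,
        loglik=ll,
        converged=converged and not separation,
        separation=separation,
        n_iter=it,
        colnames=colnames,
    )


def lrt_pvalue(ll_full: float, ll_null: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic (clipped at 0) and chi-square upper-tail P."""
    lrt = 2.0 * (ll_full - ll_null)
    if lrt < -1e-6:
        raise ValidationError(f"negative LRT {lrt}: null not nested or fit failed")
    lrt = max(lrt, 0.0)
    return lrt, float(stats.chi2.sf(lrt, df))


@dataclass
class AssociationResult:
    variant_id: str
    beta: Optional[float] = None
    se: Optional[float] = None
    lrt: Optional[float] = None
    p_value: Optional[float] = None
    eaf: Optional[float] = None  # frequency of the (alt) allele beta refers to
    n_cases: int = 0
    n_controls: int = 0
    n_dropped: int = 0
    skip_code: Optional[str] = None  # "monomorphic" | "nonconverged"
    conditional: bool = False
    genome_wide: bool = False
    chrom: str = "0"
    pos: int = 0
    ref_allele: str = "N"
    alt_allele: str = "A"
    info_score: Optional[float] = None

    @property
    def odds_ratio(self) -> Optional[float]:
        return None if self.beta is None else float(np.exp(self.beta))


@dataclass
class HeterogeneityResult:
    variant_id: str
    lambda1: float
    lambda2: float
    se_lambda1: float
    se_lambda2: float
    lrt: float
    p_het: float


@dataclass
class InteractionResult:
    variant_id: str
    coef: float
    se: float
    lrt: float
    p_value: float


def _covariate_matrix(pc: PhenoCovariates, names: Optional[Sequence[str]]):
    if not names:
        return np.empty((len(pc.samples), 0)), []
    missing = [c for c in names if c not in pc.covariates.columns]
    if missing:
        raise ValidationError(f"covariates not found: {missing}")
    return pc.covariates[list(names)].to_numpy(dtype=float), list(names)


def _as_axes(agv) -> np.ndarray:
    return np.asarray(getattr(agv, "axes", agv), dtype=float)


def test_association(
    g: np.ndarray,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    covariate_names: Optional[list] = None,
    variant_id: str = "variant",
    null_fit: Optional[FittedModel] = None,
    **meta,
) -> AssociationResult:
    """1-df LRT of a variant's additive effect, adjusted for covariates.

    Samples with missing dosage are dropped (and counted); a monomorphic
    dosage vector yields a skip code instead of a test.  ``null_fit`` may
    carry a pre-fitted no-variant model when no sample was dropped (used by
    :func:`genome_scan` to avoid refitting the null per variant).
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    C = (
        np.empty((len(y), 0))
        if covariates is None
        else np.asarray(covariates, dtype=float)
    )
    ok = ~np.isnan(g)
    n_dropped = int((~ok).sum())
    g2, y2, C2 = g[ok], y[ok], C[ok]
    res = AssociationResult(
        variant_id=variant_id,
        n_cases=int(y2.sum()),
        n_controls=int((y2 == 0).sum()),
        n_dropped=n_dropped,
        **meta,
    )
    if g2.size == 0 or g2.min() == g2.max():
        res.skip_code = "monomorphic"
        return res
    res.eaf = float(g2.mean() / 2.0)

    names = ["intercept", "genotype"] + (
        covariate_names or [f"cov{i}" for i in range(C2.shape[1])]
    )
    X_full = np.column_stack([np.ones(len(y2)), g2, C2])
    if null_fit is None or n_dropped > 0:
        null_fit = fit_logistic(y2, np.delete(X_full, 1, axis=1), check_rank=False)
    start = np.insert(null_fit.params, 1, 0.0)
    full = fit_logistic(y2, X_full, colnames=names, start=start)
    if not (full.converged and null_fit.converged):
        res.skip_code = "nonconverged"
        return res
    res.beta = float(full.params[1])
    res.se = full.se(1)
    res.lrt, res.p_value = lrt_pvalue(full.loglik, null_fit.loglik, 1)
    res.genome_wide = res.p_value < GENOME_WIDE_P
    return res


def test_heterogeneity(
    g: np.ndarray,
    phenotype: np.ndarray,
    agv,
    covariates: Optional[np.ndarray] = None,
    variant_id: str = "variant",
) -> HeterogeneityResult:
    """2-df LRT of interaction between a variant and the first two AGV.

    The null model keeps the variant's main effect and all covariates
    (including every AGV main effect), so the interaction model nests it.
    """
    axes = _as_axes(agv)
    if axes.shape[1] < 2:
        raise ValidationError("heterogeneity test needs at least two AGV")
    g = np.asarray(g, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    C = (
        np.empty((len(y), 0))
        if covariates is None
        else np.asarray(covariates, dtype=float)
    )
    ok = ~np.isnan(g)
    g, y, axes, C = g[ok], y[ok], axes[ok], C[ok]
    if g.size == 0 or g.min() == g.max():
        raise ValidationError("monomorphic variant: heterogeneity test undefined")
    x1, x2 = axes[:, 0], axes[:, 1]
    n = len(y)
    X_null = np.column_stack([np.ones(n), g, axes, C])
    X_full = np.column_stack([X_null, g * x1, g * x2])
    names = (
        ["intercept", "genotype"]
        + [f"agv{k + 1}" for k in range(axes.shape[1])]
        + [f"cov{i}" for i in range(C.shape[1])]
        + ["genotype:agv1", "genotype:agv2"]
    )
    null = fit_logistic(y, X_null, colnames=names[: X_null.shape[1]])
    start = np.concatenate([null.params, [0.0, 0.0]])
    full = fit_logistic(y, X_full, colnames=names, start=start)
    lrt, p = lrt_pvalue(full.loglik, null.loglik, 2)
    j1, j2 = X_full.shape[1] - 2, X_full.shape[1] - 1
    return HeterogeneityResult(
        variant_id=variant_id,
        lambda1=float(full.params[j1]),
        lambda2=float(full.params[j2]),
        se_lambda1=full.se(j1),
        se_lambda2=full.se(j2),
        lrt=lrt,
        p_het=p,
    )


def conditional_test(
    g: np.ndarray,
    g_cond: np.ndarray,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    variant_id: str = "variant",
    **meta,
) -> AssociationResult:
    """Association test conditioning on another variant's genotypes
    (appended to the covariates).  Conditioning on the tested variant
    itself, or on a perfect proxy, raises a collinearity error."""
    g_cond = np.asarray(g_cond, dtype=float).reshape(-1, 1)
    C = (
        g_cond
        if covariates is None
        else np.column_stack([np.asarray(covariates, dtype=float), g_cond])
    )
    res = test_association(
        g, phenotype, covariates=C, variant_id=variant_id, **meta
    )
    res.conditional = True
    return res


def test_interaction(
    g: np.ndarray,
    z: np.ndarray,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    variant_id: str = "variant",
) -> InteractionResult:
    """1-df LRT for a variant x covariate interaction, adjusting for both
    main effects (e.g. an age x SNP modification of the allelic effect)."""
    g = np.asarray(g, dtype=float)
    z = np.asarray(z, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    C = (
        np.empty((len(y), 0))
        if covariates is None
        else np.asarray(covariates, dtype=float)
    )
    ok = ~np.isnan(g) & ~np.isnan(z)
    g, z, y, C = g[ok], z[ok], y[ok], C[ok]
    n = len(y)
    X_null = np.column_stack([np.ones(n), g, z, C])
    X_full = np.column_stack([X_null, g * z])
    names = (
        ["intercept", "genotype", "z"]
        + [f"cov{i}" for i in range(C.shape[1])]
        + ["genotype:z"]
    )
    null = fit_logistic(y, X_null, colnames=names[:-1])
    full = fit_logistic(
        y, X_full, colnames=names, start=np.concatenate([null.params, [0.0]])
    )
    lrt, p = lrt_pvalue(full.loglik, null.loglik, 1)
    j = X_full.shape[1] - 1
    return InteractionResult(
        variant_id=variant_id, coef=float(full.params[j]), se=full.se(j), lrt=lrt,
        p_value=p,
    )


def genome_scan(
    gm: GenotypeMatrix,
    pheno: PhenoCovariates,
    agv=None,
    covariate_names: Optional[Sequence[str]] = None,
    het: bool = False,
    condition_on: Optional[str] = None,
):
    """Run the association test (and optionally the heterogeneity test) on
    every variant, reusing a single null fit for fully observed variants.

    Returns a list of AssociationResults; with ``het=True`` a parallel list
    of HeterogeneityResults (None where skipped) is returned as well.
    """
    y = pheno.phenotype.astype(float)
    C, cnames = _covariate_matrix(pheno, covariate_names)
    axes = None
    if agv is not None:
        axes = _as_axes(agv)
        C = np.column_stack([axes, C]) if C.size else axes
        cnames = [f"agv{k + 1}" for k in range(axes.shape[1])] + cnames
    if condition_on is not None:
        ids = [v.id for v in gm.variants]
        if condition_on not in ids:
            raise ValidationError(f"conditioning variant {condition_on!r} not found")
        gc = gm.dosage[:, ids.index(condition_on)]
        C = np.column_stack([C, gc]) if C.size else gc.reshape(-1, 1)
        cnames = cnames + [f"cond:{condition_on}"]

    X_null = np.column_stack([np.ones(len(y)), C]) if C.size else np.ones((len(y), 1))
    null_fit = fit_logistic(y, X_null, colnames=["intercept"] + cnames)

    results, het_results = [], []
    for j, v in enumerate(gm.variants):
        if condition_on is not None and v.id == condition_on:
            continue
        g = gm.dosage[:, j]
        res = test_association(
            g, y, covariates=C if C.size else None, covariate_names=cnames,
            variant_id=v.id, null_fit=null_fit,
            chrom=v.chrom, pos=v.pos, ref_allele=v.ref, alt_allele=v.alt,
            info_score=v.info_score, conditional=condition_on is not None,
        )
        results.append(res)
        if het:
            if res.skip_code is not None or axes is None:
                het_results.append(None)
            else:
                extra = C[:, axes.shape[1]:] if C.shape[1] > axes.shape[1] else None
                het_results.append(
                    test_heterogeneity(g, y, axes, covariates=extra, variant_id=v.id)
                )
    return (results, het_results) if het else results
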