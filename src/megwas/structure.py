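"""Population-structure inference: LD pruning, GRM construction, PCA-derived
axes of genetic variation (AGV), covariate screening, and genomic control.

The AGV are the leading eigenvectors of a genetic relatedness matrix (GRM).
Individuals of diverse ancestry separate along the first few axes, so
including the AGV as covariates in association models absorbs confounding
between phenotype and ancestry.  Two GRM flavours are provided: the
standardized (1/M) Z Z' form whose eigenvectors are the classical genotype
principal components, and the method-of-moments pi-hat matrix used for
relatedness screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .geno_io import GenotypeMatrix, ValidationError
from .qc import estimate_pihat

#: median of the 1-df chi-square distribution, the genomic-control denominator
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class GRM:
    matrix: np.ndarray  # samples x samples, symmetric
    samples: list
    kind: str  # "standardized" | "pihat"
    provenance: dict = field(default_factory=dict)


@dataclass
class AGVMatrix:
    """Samples x K orthonormal axes of genetic variation with eigenvalues."""

    samples: list
    axes: np.ndarray  # (n_samples, K), orthonormal columns
    eigenvalues: np.ndarray  # (K,), non-increasing
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axes = np.asarray(self.axes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValidationError("eigenvalues must be non-increasing")

    @property
    def K(self) -> int:
        return self.axes.shape[1]


def _imputed_dosage(gm: GenotypeMatrix) -> np.ndarray:
    """Dosages with missing entries replaced by the variant mean.

    Returns the stored array itself when nothing is missing (no copy)."""
    d = gm.dosage
    if np.isnan(d).any():
        d = d.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
    return d


def ld_prune(
    gm: GenotypeMatrix, r2_max: float = 0.01, window: int = 50, step: int = 5
) -> np.ndarray:
    """Greedy left-to-right LD pruning.

    Scanning variants in input order, a variant is dropped when its squared
    Pearson correlation with any already-retained variant inside the
    trailing ``window`` reaches ``r2_max``.  All-missing and constant
    variants are excluded up front.  Deterministic for a fixed input order.
    Returns the indices of kept variants.
    """
    if not (0 < r2_max <= 1):
        raise ValidationError("r2_max must lie in (0, 1]")
    if window < 2:
        raise ValidationError("window must be at least 2")
    del step  # retained for CLI compatibility; the trailing window scan is stepless
    d = _imputed_dosage(gm)
    sd = d.std(axis=0)
    usable = np.flatnonzero(sd > 0)
    z = (d[:, usable] - d[:, usable].mean(axis=0)) / sd[usable]
    n = z.shape[0]
    kept: list[int] = []  # positions within `usable`
    for j in range(len(usable)):
        in_window = [k for k in kept if usable[j] - usable[k] < window]
        drop = False
        for k in in_window:
            r = float(z[:, k] @ z[:, j]) / n
            if r * r >= r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
    return usable[kept]


def compute_grm(gm_pruned: GenotypeMatrix, kind: str = "standardized") -> GRM:
    """Build a GRM from (pruned) genotypes.

    ``standardized``: (1/M) Z Z' with Z the column-centred, column-scaled
    dosage matrix (missing entries mean-imputed before centring).
    ``pihat``: pairwise method-of-moments IBD estimates (see :mod:`megwas.qc`).
    """
    prov = {"n_variants": gm_pruned.n_variants}
    if kind == "pihat":
        mat = estimate_pihat(gm_pruned)
    elif kind == "standardized":
        z = _standardize(_imputed_dosage(gm_pruned))
        mat = (z @ z.T) / z.shape[1]
    else:
        raise ValidationError(f"unknown GRM kind {kind!r}")
    return GRM(matrix=mat, samples=list(gm_pruned.samples), kind=kind, provenance=prov)


def _standardize(d: np.ndarray) -> np.ndarray:
    mu = d.mean(axis=0)
    sd = d.std(axis=0)
    keep = sd > 0
    if not keep.all():
        d, mu, sd = d[:, keep], mu[keep], sd[keep]
    z = d - mu  # single new allocation; scaled in place
    z /= sd
    return z


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    # sign convention: the largest-magnitude loading of each axis is positive
    idx = np.argmax(np.abs(axes), axis=0)
    signs = np.sign(axes[idx, np.arange(axes.shape[1])])
    signs[signs == 0] = 1.0
    return axes * signs


def compute_agv(grm: GRM, K: int) -> AGVMatrix:
    """Top-K eigenvectors of the GRM, unit norm, eigenvalue-sorted.

    If K exceeds the numerical rank, only rank-many axes are returned
    (with a warning).
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    n = grm.matrix.shape[0]
    K = min(K, n)
    vals, vecs = linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank = int((vals > max(vals[0], 0) * 1e-10).sum())
    if K > rank:
        warnings.warn(
            f"requested {K} axes but GRM rank is {rank}; returning {rank}",
            stacklevel=2,
        )
        K = rank
    return AGVMatrix(
        samples=list(grm.samples),
        axes=_fix_signs(vecs[:, :K]),
        eigenvalues=vals[:K],
        provenance={"grm_kind": grm.kind, **grm.provenance},
    )


def compute_agv_from_genotypes(gm: GenotypeMatrix, K: int) -> AGVMatrix:
    """AGV via thin SVD of the standardized dosage matrix.

    Mathematically identical to ``compute_agv(compute_grm(gm), K)`` for the
    standardized GRM, but never materialises the samples x samples matrix,
    so it scales to cohort-sized sample counts.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    z = _standardize(_imputed_dosage(gm))
    if K + 10 < min(z.shape) // 2 and min(z.shape) > 500:
        # large panel: randomized subspace iteration for the leading
        # triplets only; deterministic (fixed sketching seed), and the
        # power iterations make the weak within-continent axes accurate
        from sklearn.utils.extmath import randomized_svd

        u, s, _ = randomized_svd(
            z, n_components=K + 10, n_iter=8, random_state=0
        )
    else:
        u, s, _ = linalg.svd(z, full_matrices=False)
    vals = s**2 / z.shape[1]
    rank = int((s > max(s[0], 0) * 1e-10).sum())
    if K > rank:
        warnings.warn(
            f"requested {K} axes but genotype rank is {rank}; returning {rank}",
            stacklevel=2,
        )
        K = rank
    return AGVMatrix(
        samples=list(gm.samples),
        axes=_fix_signs(u[:, :K]),
        eigenvalues=vals[:K],
        provenance={"grm_kind": "standardized", "n_variants": gm.n_variants},
    )


def screen_agv(
    agv: AGVMatrix, phenotype: np.ndarray, n_test: int = 20, alpha: float = 0.05
) -> np.ndarray:
    """Indices of axes (among the first ``n_test``) associated with the
    phenotype at P < ``alpha``, by single-covariate logistic LRT."""
    from .assoc import fit_logistic

    y = np.asarray(phenotype, dtype=float)
    n_test = min(n_test, agv.K)
    ones = np.ones((len(y), 1))
    ll_null = fit_logistic(y, ones).loglik
    retained = []
    for k in range(n_test):
        X = np.column_stack([ones, agv.axes[:, k]])
        fit = fit_logistic(y, X)
        lrt = max(2.0 * (fit.loglik - ll_null), 0.0)
        p = stats.chi2.sf(lrt, 1)
        if p < alpha:
            retained.append(k)
    return np.asarray(retained, dtype=int)


def genomic_control(chisq_1df: np.ndarray) -> float:
    """Genomic-control inflation factor: median test statistic divided by
    the 1-df chi-square median (0.4549...)."""
    chisq_1df = np.asarray(chisq_1df, dtype=float)
    if chisq_1df.size == 0:
        raise ValidationError("genomic control needs at least one statistic")
    return float(np.median(chisq_1df) / CHI2_1DF_MEDIAN)


def lambda_1000(lam: float, n_cases: int, n_controls: int) -> float:
    """Rescale an inflation factor to the equivalent study of 1000 cases and
    1000 controls: 1 + (lambda - 1) * 500 * (1/n_cases + 1/n_controls)."""
    if n_cases < 1 or n_controls < 1:
        raise ValidationError("need at least one case and one control")
    return 1.0 + (lam - 1.0) * 500.0 * (1.0 / n_cases + 1.0 / n_controls)
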