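"""Fixed-effects meta-analysis across homogeneous population groups.

The comparator to the pooled multi-ethnic model: each population is tested
separately (adjusting for its own 'population-specific' AGV), per-study
effects are combined by inverse-variance weighting, and between-population
heterogeneity is assessed with Cochran's Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .assoc import AssociationResult, test_association
from .geno_io import GenotypeMatrix, ValidationError
from .structure import compute_agv_from_genotypes


@dataclass
class MetaResult:
    study_betas: np.ndarray
    study_ses: np.ndarray
    beta: float
    se: float
    z: float
    p_value: float
    q: Optional[float] = None
    q_df: Optional[int] = None
    q_p: Optional[float] = None
    single_study: bool = False
    dropped: list = field(default_factory=list)  # (study, reason)


def ivw_meta(betas, ses) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling.

    weights w_i = 1/se_i^2; pooled beta = sum(w b)/sum(w); pooled
    SE = sum(w)^(-1/2); two-sided normal P.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1 or b.size < 1:
        raise ValidationError("betas and ses must be equal-length 1-d, length >= 1")
    if not (np.isfinite(b).all() and np.isfinite(s).all()) or (s <= 0).any():
        raise ValidationError("betas/ses must be finite with ses > 0")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        study_betas=b, study_ses=s, beta=beta, se=se, z=z, p_value=p,
        single_study=b.size == 1,
    )


def cochran_q(betas, ses) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic.

    Q = sum w_i (b_i - b_pooled)^2 with the IVW pooled estimate; chi-square
    with k-1 df under homogeneity.  A single study gives Q=0 with P
    reported as 1 (df 0; heterogeneity is undefined there).
    """
    pooled = ivw_meta(betas, ses)
    b, s = pooled.study_betas, pooled.study_ses
    w = 1.0 / s**2
    q = float((w * (b - pooled.beta) ** 2).sum())
    df = b.size - 1
    p = float(stats.chi2.sf(q, df)) if df >= 1 else 1.0
    return q, df, p


def meta_analyse(betas, ses) -> MetaResult:
    """IVW pooling plus Cochran's Q in one result."""
    res = ivw_meta(betas, ses)
    res.q, res.q_df, res.q_p = cochran_q(betas, ses)
    return res


def per_population_scan(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    pop_labels,
    n_agv: int = 4,
    agv_source: Optional[GenotypeMatrix] = None,
) -> dict:
    """Association scan within each population separately.

    AGV are recomputed per population from ``agv_source`` (default: the
    tested matrix itself) so they capture within-population structure only.
    Populations with a single phenotype class are dropped with a reason
    code — an all-control population carries no case-control contrast.

    Returns ``{population: list[AssociationResult] | (None, reason)}``.
    """
    pop_labels = np.asarray(pop_labels)
    y = np.asarray(phenotype, dtype=float)
    src = agv_source if agv_source is not None else gm
    out: dict = {}
    for pop in dict.fromkeys(pop_labels.tolist()):  # preserve first-seen order
        idx = np.flatnonzero(pop_labels == pop)
        y_p = y[idx]
        if y_p.min() == y_p.max():
            out[pop] = (None, "single_phenotype_class")
            continue
        axes = compute_agv_from_genotypes(src.subset(sample_idx=idx), n_agv).axes
        sub = gm.subset(sample_idx=idx)
        results = []
        for j, v in enumerate(sub.variants):
            results.append(
                test_association(
                    sub.dosage[:, j], y_p, covariates=axes, variant_id=v.id,
                    chrom=v.chrom, pos=v.pos, ref_allele=v.ref, alt_allele=v.alt,
                    info_score=v.info_score,
                )
            )
        out[pop] = results
    return out


def meta_from_scans(per_pop: dict, variant_index: int = 0) -> MetaResult:
    """Pool one variant's per-population results, dropping populations that
    were skipped (single class, monomorphic, or non-converged)."""
    betas, ses, dropped = [], [], []
    for pop, entry in per_pop.items():
        if isinstance(entry, tuple):
            dropped.append((pop, entry[1]))
            continue
        r: AssociationResult = entry[variant_index]
        if r.skip_code is not None:
            dropped.append((pop, r.skip_code))
            continue
        betas.append(r.beta)
        ses.append(r.se)
    if not betas:
        raise ValidationError("no population contributed a usable estimate")
    res = meta_analyse(betas, ses)
    res.dropped = dropped
    return res
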