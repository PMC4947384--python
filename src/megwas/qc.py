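"""Genotype and sample quality control.

Filters follow standard case-control GWAS practice: per-sample then
per-variant call-rate thresholds, a Hardy-Weinberg exact test, minor-allele
frequency and imputation-quality floors, palindromic-variant flagging, and
removal of cryptic relatedness via method-of-moments IBD (pi-hat) estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log
from typing import Optional

import numpy as np

from .geno_io import GenotypeMatrix, ValidationError


@dataclass
class QCReport:
    """Per-sample/per-variant QC metrics and exclusions with reason codes."""

    sample_call_rate: dict = field(default_factory=dict)
    variant_call_rate: dict = field(default_factory=dict)
    excluded_samples: list = field(default_factory=list)  # (sample_id, reason)
    excluded_variants: list = field(default_factory=list)  # (variant_id, reason)
    high_pihat_pairs: list = field(default_factory=list)  # (id1, id2, pihat)


class NoDataError(ValueError):
    """Every sample or variant was removed by a filter."""


def sample_call_rates(gm: GenotypeMatrix) -> np.ndarray:
    if gm.n_variants == 0:
        return np.ones(gm.n_samples)
    return 1.0 - gm.missing.mean(axis=1)


def variant_call_rates(gm: GenotypeMatrix) -> np.ndarray:
    if gm.n_samples == 0:
        return np.ones(gm.n_variants)
    return 1.0 - gm.missing.mean(axis=0)


def call_rate_filter(
    gm: GenotypeMatrix, sample_min: float = 0.97, variant_min: float = 0.95
):
    """Drop samples with call rate < ``sample_min``, then variants with call
    rate < ``variant_min`` (both strict), in that order.

    Returns the filtered matrix and a :class:`QCReport` listing removals.
    """
    if not (0 < sample_min <= 1) or not (0 < variant_min <= 1):
        raise ValidationError("call-rate thresholds must lie in (0, 1]")
    report = QCReport()
    scr = sample_call_rates(gm)
    report.sample_call_rate = dict(zip(gm.samples, scr.tolist()))
    keep_s = np.flatnonzero(scr >= sample_min)
    for i in np.flatnonzero(scr < sample_min):
        report.excluded_samples.append((gm.samples[i], "low_call_rate"))
    gm = gm.subset(sample_idx=keep_s)
    if gm.n_samples == 0:
        raise NoDataError("all samples removed by call-rate filter")

    vcr = variant_call_rates(gm)
    report.variant_call_rate = dict(
        zip((v.id for v in gm.variants), vcr.tolist())
    )
    keep_v = np.flatnonzero(vcr >= variant_min)
    for j in np.flatnonzero(vcr < variant_min):
        report.excluded_variants.append((gm.variants[j].id, "low_call_rate"))
    gm = gm.subset(variant_idx=keep_v)
    if gm.n_variants == 0:
        raise NoDataError("all variants removed by call-rate filter")
    return gm, report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test P value.

    Conditional on the observed allele counts, heterozygote counts of the
    same parity are enumerated and the probabilities of all configurations
    no more likely than the observed one are summed (plain, not mid-p).
    Monomorphic input returns 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValidationError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # one allele's count; symmetry makes the choice moot
    n_A = 2 * n - n_a
    minor = min(n_a, n_A)
    if minor == 0:
        return 1.0

    def log_prob(h: int) -> float:
        # P(het=h | n, allele counts) = n! 2^h / (hom1! h! hom2!) * na! nA! / (2n)!
        hom_minor = (minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            lgamma(n + 1)
            - lgamma(hom_minor + 1)
            - lgamma(h + 1)
            - lgamma(hom_major + 1)
            + h * log(2.0)
            + lgamma(n_a + 1)
            + lgamma(n_A + 1)
            - lgamma(2 * n + 1)
        )

    hs = range(minor % 2, minor + 1, 2)
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[list(hs).index(n_Aa)]
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor-allele frequency: mean(dosage)/2 over non-missing
    entries, folded to [0, 0.5]."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(gm.dosage, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def alt_allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nanmean(gm.dosage, axis=0) / 2.0


def maf_filter(
    gm: GenotypeMatrix, min_maf: float = 0.005, min_info: Optional[float] = 0.4
):
    """Drop variants with MAF < ``min_maf`` or (when an info score is
    recorded) info < ``min_info``, both strict."""
    report = QCReport()
    m = maf(gm)
    keep = []
    for j, v in enumerate(gm.variants):
        if np.isnan(m[j]) or m[j] < min_maf:
            report.excluded_variants.append((v.id, "low_maf"))
        elif (
            min_info is not None
            and v.info_score is not None
            and v.info_score < min_info
        ):
            report.excluded_variants.append((v.id, "low_info"))
        else:
            keep.append(j)
    return gm.subset(variant_idx=keep), report


def is_palindromic(ref: str, alt: str) -> bool:
    """True for A/T and C/G variants, whose strand cannot be resolved."""
    pair = {ref.upper(), alt.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def hard_call(dosage: np.ndarray) -> np.ndarray:
    """Round dosages to 0/1/2 at the 0.5/1.5 cut points (NaN preserved)."""
    g = np.where(dosage < 0.5, 0.0, np.where(dosage < 1.5, 1.0, 2.0))
    return np.where(np.isnan(dosage), np.nan, g)


def estimate_pihat(gm_pruned: GenotypeMatrix) -> np.ndarray:
    """Pairwise pi-hat (proportion of genome shared IBD) by the
    method-of-moments IBS decomposition.

    Expected identity-by-state counts given the sample allele frequencies
    are inverted to P(IBD=0/1/2) per pair; pi-hat = P(IBD=2) + P(IBD=1)/2,
    truncated to [0, 1].  Dosages are hard-called first; intended for LD
    pruned, common variants.
    """
    if gm_pruned.n_samples < 2:
        raise ValidationError("pi-hat needs at least two samples")
    g = hard_call(gm_pruned.dosage)
    p = np.nanmean(g, axis=0) / 2.0
    ok = ~np.isnan(p) & (p > 0) & (p < 1)
    g = g[:, ok]
    p = p[ok]
    q = 1.0 - p
    # per-variant expected IBS probabilities under each IBD state
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2

    n = gm_pruned.n_samples
    pihat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(g[i]) & ~np.isnan(g[j])
            if both.sum() == 0:
                pihat[i, j] = pihat[j, i] = np.nan
                continue
            d = np.abs(g[i, both] - g[j, both])
            n_ibs0 = float((d == 2).sum())
            n_ibs1 = float((d == 1).sum())
            n_ibs2 = float((d == 0).sum())
            E0_0, E1_0, E2_0 = e0_ibd0[both].sum(), e1_ibd0[both].sum(), e2_ibd0[both].sum()
            E1_1, E2_1 = e1_ibd1[both].sum(), e2_ibd1[both].sum()
            M = float(both.sum())
            P0 = n_ibs0 / E0_0 if E0_0 > 0 else 0.0
            P1 = (n_ibs1 - P0 * E1_0) / E1_1 if E1_1 > 0 else 0.0
            P2 = (n_ibs2 - P0 * E2_0 - P1 * E2_1) / M
            ph = min(max(P2 + 0.5 * P1, 0.0), 1.0)
            pihat[i, j] = pihat[j, i] = ph
    return pihat


def remove_related(
    pihat: np.ndarray, call_rates: np.ndarray, threshold: float = 0.2
) -> np.ndarray:
    """Greedy relatedness pruning: while any pair exceeds ``threshold``,
    drop the involved sample with the lowest call rate (ties broken by
    keeping the earlier sample).  Returns indices of kept samples."""
    pihat = np.asarray(pihat, dtype=float)
    n = pihat.shape[0]
    if pihat.shape != (n, n):
        raise ValidationError("pihat must be square")
    adj = np.nan_to_num(pihat, nan=0.0) > threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    while True:
        deg = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        cand = np.flatnonzero(alive & (deg > 0))
        if cand.size == 0:
            break
        # lowest call rate; among ties drop the later sample index
        cr = np.asarray(call_rates)[cand]
        worst = cand[cr == cr.min()][-1]
        alive[worst] = False
    return np.flatnonzero(alive)
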