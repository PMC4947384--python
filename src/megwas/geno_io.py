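"""Genotype, phenotype and summary-statistic I/O.

Dosages are stored as a samples x variants float array in [0, 2], with
``numpy.nan`` marking missing entries.  Coordinates are 1-based as in VCF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a data contract (range, alignment, uniqueness)."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    info_score: Optional[float] = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``dosage[i, j]`` is the expected count of the alternative allele for
    sample ``i`` at variant ``j``; missing entries are NaN.
    """

    samples: list
    variants: list  # of VariantRecord
    dosage: np.ndarray  # float, shape (n_samples, n_variants)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage)
        if not np.issubdtype(self.dosage.dtype, np.floating):
            self.dosage = self.dosage.astype(float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample IDs are not unique")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValidationError("variant (chrom,pos,ref,alt) tuples are not unique")
        if self.dosage.size:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                lo, hi = np.nanmin(self.dosage), np.nanmax(self.dosage)
            if not np.isnan(lo) and (lo < 0 or hi > 2):
                raise ValidationError("dosage values outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=[self.variants[j] for j in vi],
            dosage=self.dosage[np.ix_(si, vi)],
        )


@dataclass
class PhenoCovariates:
    """Binary phenotype plus named covariate columns, sample-ID keyed."""

    samples: list
    phenotype: np.ndarray  # values in {0, 1}
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.phenotype = np.asarray(self.phenotype)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample IDs are not unique")
        if self.phenotype.shape != (len(self.samples),):
            raise ValidationError("phenotype length does not match samples")
        bad = ~np.isin(self.phenotype, [0, 1])
        if bad.any():
            raise ValidationError(
                f"phenotype values outside {{0,1}}: {np.unique(self.phenotype[bad])}"
            )
        self.phenotype = self.phenotype.astype(int)
        if len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=range(len(self.samples)))
        elif len(self.covariates) != len(self.samples):
            raise ValidationError("covariate table length does not match samples")
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())


def align_samples(gm: GenotypeMatrix, pc: PhenoCovariates):
    """Join genotype and phenotype stores on sample ID.

    Returns ``(gm', pc')`` restricted to the shared samples, in the genotype
    matrix's order; every analysed sample appears exactly once in both.
    """
    pheno_pos = {s: i for i, s in enumerate(pc.samples)}
    keep = [i for i, s in enumerate(gm.samples) if s in pheno_pos]
    if not keep:
        raise ValidationError("no samples shared between genotypes and phenotypes")
    gm2 = gm.subset(sample_idx=keep)
    order = [pheno_pos[s] for s in gm2.samples]
    pc2 = PhenoCovariates(
        samples=[pc.samples[i] for i in order],
        phenotype=pc.phenotype[order],
        covariates=pc.covariates.iloc[order],
    )
    return gm2, pc2


# ---------------------------------------------------------------------------
# readers / writers

def read_vcf(path, field: str = "GT") -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    ``field="GT"`` converts hard genotypes to 0/1/2 dosages (missing or
    half-called -> NaN); ``field="DS"`` takes the dosage FORMAT field,
    clamped to [0, 2].  Multi-allelic records are skipped with a warning.
    """
    from cyvcf2 import VCF

    if field not in ("GT", "DS"):
        raise ValidationError(f"field must be GT or DS, got {field!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    import logging

    log = logging.getLogger(__name__)
    for rec in vcf:
        if len(rec.ALT) != 1:
            log.warning(
                "skipping multi-allelic record %s:%s %s", rec.CHROM, rec.POS, rec.ALT
            )
            continue
        if field == "GT":
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            col = np.empty(len(samples))
            for i, gt in enumerate(rec.genotypes):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    col[i] = np.nan
                else:
                    col[i] = float((a > 0) + (b > 0))
        else:
            ds = rec.format("DS")
            if ds is None:
                raise ValidationError(f"DS field absent at {rec.CHROM}:{rec.POS}")
            col = np.clip(np.asarray(ds, dtype=float).reshape(-1), 0.0, 2.0)
        info = rec.INFO.get("INFO")
        variants.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ref=rec.REF,
                alt=rec.ALT[0],
                info_score=float(info) if info is not None else None,
            )
        )
        columns.append(col)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def read_dosage_table(path) -> GenotypeMatrix:
    """Read a tab-delimited dosage matrix (header = variant IDs, first
    column = sample ID, entries real or NA)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except pd.errors.ParserError as e:
        raise ParseError(str(e)) from e
    dosage = df.to_numpy(dtype=float)
    present = dosage[~np.isnan(dosage)]
    if present.size and (present.min() < 0 or present.max() > 2):
        raise ValidationError("dosage entries outside [0, 2]")
    variants = [_variant_from_id(str(c)) for c in df.columns]
    return GenotypeMatrix(
        samples=[str(s) for s in df.index], variants=variants, dosage=dosage
    )


def _variant_from_id(vid: str) -> VariantRecord:
    # dosage tables carry only an ID; synthesise chrom:pos if encoded as such
    if ":" in vid:
        chrom, _, rest = vid.partition(":")
        pos = rest.split("_")[0]
        if pos.isdigit():
            return VariantRecord(chrom=chrom, pos=int(pos), id=vid, ref="N", alt=vid)
    return VariantRecord(chrom="0", pos=0, id=vid, ref="N", alt=vid)


def write_dosage_table(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosage, index=gm.samples, columns=[v.id for v in gm.variants])
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_pheno(path, pheno_col: str = "phenotype") -> PhenoCovariates:
    """Read a tab-delimited phenotype/covariate table.

    First column is the sample ID; ``pheno_col`` must contain 0/1 (NA rows
    are dropped); remaining columns are kept as named real covariates.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.shape[1] < 2:
        raise ParseError("phenotype table needs a sample-ID and a phenotype column")
    id_col = df.columns[0]
    if pheno_col not in df.columns:
        raise ValidationError(f"phenotype column {pheno_col!r} not found")
    df = df.dropna(subset=[pheno_col])
    ph = df[pheno_col].to_numpy()
    if not np.isin(ph, [0, 1]).all():
        raise ValidationError(
            f"phenotype values outside {{0,1,NA}}: {sorted(set(ph) - {0, 1})}"
        )
    cov = df.drop(columns=[id_col, pheno_col]).astype(float)
    return PhenoCovariates(
        samples=[str(s) for s in df[id_col]], phenotype=ph.astype(int), covariates=cov
    )


def write_results(results: Sequence, path) -> None:
    """Write association results as tab-delimited summary statistics.

    Columns: variant id, chrom, pos, risk/other allele, risk-allele
    frequency, OR with 95% CI, P, P_het (when available), imputation info.
    The risk allele is the allele whose odds ratio exceeds 1.
    """
    rows = []
    for r in results:
        beta = r.beta
        raf = r.eaf
        risk, other = r.alt_allele, r.ref_allele
        if beta is not None and beta < 0:
            beta = -beta
            raf = None if raf is None else 1.0 - raf
            risk, other = other, risk
        if beta is None or r.se is None:
            or_, lo, hi = math.nan, math.nan, math.nan
        else:
            or_ = math.exp(beta)
            lo = math.exp(beta - 1.96 * r.se)
            hi = math.exp(beta + 1.96 * r.se)
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "risk_allele": risk,
                "other_allele": other,
                "raf": raf,
                "odds_ratio": or_,
                "ci_lower": lo,
                "ci_upper": hi,
                "p_value": r.p_value,
                "p_het": getattr(r, "p_het", None),
                "info": r.info_score,
            }
        )
    cols = [
        "variant_id", "chrom", "pos", "risk_allele", "other_allele", "raf",
        "odds_ratio", "ci_lower", "ci_upper", "p_value", "p_het", "info",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, na_rep="NA")
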