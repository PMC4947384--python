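import numpy as np
import pytest

from megwas import GenotypeMatrix, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_gm(dosage, samples=None, ids=None, info=None):
    """Build a GenotypeMatrix from a plain array with synthetic metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = samples or [f"s{i}" for i in range(n)]
    ids = ids or [f"v{j}" for j in range(m)]
    variants = [
        VariantRecord(
            chrom="1", pos=j + 1, id=ids[j], ref="A", alt="G",
            info_score=None if info is None else info[j],
        )
        for j in range(m)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


@pytest.fixture
def gm_factory():
    return make_gm


def write_vcf(path, samples, records, fmt="GT"):
    """Write a minimal VCF; records are (chrom, pos, id, ref, alt, values)."""
    lines = ["##fileformat=VCFv4.2"]
    if fmt == "DS":
        lines.append(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">'
        )
    else:
        lines.append(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for chrom, pos, vid, ref, alt, values in records:
        vals = "\t".join(str(v) for v in values)
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t{vals}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def vcf_factory():
    return write_vcf
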