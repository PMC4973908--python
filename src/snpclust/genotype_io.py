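"""Readers and writers for standard genotype formats.

PLINK 1 binary (bed/bim/fam, SNP-major) is decoded directly: the format is a
3-byte magic followed by 2-bit genotype codes, SNP by SNP.  The counted
allele is the bim A1 allele, so a ``00`` code (homozygous A1) maps to
genotype 2.  VCF is read through :mod:`cyvcf2`; the ALT allele is counted.
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, FeatureMatrix, GenotypeData, GenotypeDataError

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _with_ext(prefix, ext):
    return Path(str(prefix) + ext)

# 2-bit PLINK codes -> additive dosage of A1 (counted allele).
# 00 = hom A1 -> 2, 01 = missing, 10 = het -> 1, 11 = hom A2 -> 0.
_CODE_TO_GENO = np.array([2, MISSING, 1, 0], dtype=np.int8)
_GENO_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _decode_byte_table() -> np.ndarray:
    """(256, 4) table mapping one packed byte to four genotype calls."""
    table = np.empty((256, 4), dtype=np.int8)
    for byte in range(256):
        for k in range(4):
            table[byte, k] = _CODE_TO_GENO[(byte >> (2 * k)) & 0b11]
    return table


_BYTE_TABLE = _decode_byte_table()


def read_plink(prefix: str | os.PathLike) -> GenotypeData:
    """Read a PLINK bed/bim/fam trio into a :class:`GenotypeData`.

    fam phenotypes follow the PLINK convention: 1 = control (0), 2 = case
    (1), 0 or -9 = missing.  SNPs are returned sorted by (chrom, pos_bp).
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        _with_ext(prefix, ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "allele_a1", "allele_a2"],
        dtype={"chrom": str, "snp_id": str, "allele_a1": str, "allele_a2": str},
    )
    fam = pd.read_csv(
        _with_ext(prefix, ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(_with_ext(prefix, ".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeDataError(f"{prefix}.bed: bad magic; not a SNP-major PLINK 1 bed file")
    bytes_per_snp = (n + 3) // 4
    payload = raw[3:]
    if payload.size != bytes_per_snp * m:
        raise GenotypeDataError(
            f"{prefix}.bed payload has {payload.size} bytes, expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    decoded = _BYTE_TABLE[payload.reshape(m, bytes_per_snp)]  # (m, bytes, 4)
    genotypes = decoded.reshape(m, bytes_per_snp * 4)[:, :n].T.copy()

    pheno = fam["pheno"].map({1: 0.0, 2: 1.0}).astype(float)
    samples = pd.DataFrame(
        {
            "sample_id": fam["iid"],
            "phenotype": pheno,
            "population_label": pd.Series([None] * n, dtype=object),
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos_bp": bim["pos_bp"].astype(np.int64),
            # A1 is the counted allele (allele_b of the additive coding).
            "allele_a": bim["allele_a2"],
            "allele_b": bim["allele_a1"],
        }
    )
    return GenotypeData(genotypes, snps, samples).sorted_by_position()


def write_plink(g: GenotypeData, prefix: str | os.PathLike) -> None:
    """Write ``g`` as a PLINK bed/bim/fam trio (SNP-major bed v1.0)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.n_samples, g.n_snps
    bim = pd.DataFrame(
        {
            "chrom": g.snps["chrom"],
            "snp_id": g.snps["snp_id"],
            "cm": 0,
            "pos_bp": g.snps["pos_bp"],
            "a1": g.snps["allele_b"],
            "a2": g.snps["allele_a"],
        }
    )
    bim.to_csv(_with_ext(prefix, ".bim"), sep="\t", header=False, index=False)
    pheno = g.samples["phenotype"].map({0.0: 1, 1.0: 2}).fillna(-9).astype(int)
    fam = pd.DataFrame(
        {
            "fid": g.samples["sample_id"],
            "iid": g.samples["sample_id"],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": pheno,
        }
    )
    fam.to_csv(_with_ext(prefix, ".fam"), sep="\t", header=False, index=False)

    codes = np.empty_like(g.genotypes, dtype=np.uint8)
    for geno, code in _GENO_TO_CODE.items():
        codes[g.genotypes == geno] = code
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)  # pad bits are 0 per format
    padded[:, :n] = codes.T
    packed = (
        padded.reshape(m, bytes_per_snp, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(_with_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: str | os.PathLike) -> GenotypeData:
    """Read a (plain or bgzipped) VCF with GT fields.

    Biallelic SNP records only; multi-allelic or non-SNP records are skipped
    with a counted warning.  ALT is the counted allele.  Unsorted positions
    are sorted with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise GenotypeDataError(f"{path}: VCF has no GT FORMAT field")
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = variant.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        snp_id = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        meta.append((snp_id, variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multi-allelic/non-SNP records")
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"])
    genotypes = np.vstack(rows).T if rows else np.empty((len(sample_ids), 0), dtype=np.int8)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "phenotype": np.full(len(sample_ids), np.nan),
            "population_label": pd.Series([None] * len(sample_ids), dtype=object),
        }
    )
    unsorted = (
        snps.groupby("chrom", sort=False)["pos_bp"].apply(lambda s: not s.is_monotonic_increasing).any()
    )
    if unsorted:
        warnings.warn(f"{path}: positions not sorted; sorting by (chrom, pos)")
    return GenotypeData(genotypes, snps, samples).sorted_by_position()


def attach_sample_table(g: GenotypeData, path: str | os.PathLike) -> GenotypeData:
    """Merge a sidecar TSV (sample_id [, phenotype] [, population_label])."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    samples = g.samples.drop(
        columns=[c for c in ("phenotype", "population_label") if c in table.columns]
    ).merge(table, on="sample_id", how="left")
    if "population_label" not in samples.columns:
        samples["population_label"] = pd.Series([None] * len(samples), dtype=object)
    if "phenotype" not in samples.columns:
        samples["phenotype"] = np.nan
    return GenotypeData(g.genotypes, g.snps, samples[list(g.samples.columns)])


def _feature_column_name(row: pd.Series) -> str:
    if row["kind"] == "snp":
        return f"snp:{row['feature_id']}"
    return f"hap:{row['chrom']}:{int(row['start_bp'])}-{int(row['end_bp'])}:{int(row['component'])}"


def write_feature_table(features: FeatureMatrix, path: str | os.PathLike) -> None:
    """Write a FeatureMatrix as TSV: one row per sample, one column per feature.

    The header encodes the feature type (``snp:<id>`` or
    ``hap:<chrom>:<start>-<end>:<pc>``); the counted allele / minor haplotype
    class convention is noted in a leading comment line.
    """
    cols = [_feature_column_name(row) for _, row in features.features.iterrows()]
    df = pd.DataFrame(features.values, columns=cols)
    df.insert(0, "sample_id", features.sample_ids.to_numpy())
    with open(path, "w") as fh:
        fh.write("# values: counted-allele dosage (snp) or minor haplotype-class count (hap), in {0,1,2}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_feature_table(path: str | os.PathLike) -> FeatureMatrix:
    """Inverse of :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    sample_ids = df["sample_id"].astype(str)
    values = df.drop(columns=["sample_id"]).to_numpy(dtype=np.int8)
    records = []
    for name in df.columns[1:]:
        kind, rest = name.split(":", 1)
        if kind == "snp":
            records.append((rest, "snp", None, np.nan, np.nan, np.nan, 1))
        else:
            chrom, span, pc = rest.rsplit(":", 2)
            start, end = span.split("-")
            records.append((name, "hap", chrom, int(start), int(end), int(pc), np.nan))
    features = pd.DataFrame(
        records,
        columns=["feature_id", "kind", "chrom", "start_bp", "end_bp", "component", "n_snps"],
    )
    return FeatureMatrix(values, features, sample_ids)
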