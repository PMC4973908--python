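"""Core in-memory containers shared by all pipeline stages.

Genotypes are stored additively: 0, 1, 2 copies of the counted allele
(``allele_b``, i.e. the PLINK A1 / VCF ALT allele), with :data:`MISSING`
(-1) for unobserved calls.  SNP and sample metadata travel as pandas
DataFrames so that downstream stages can filter rows/columns with plain
boolean indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the int8 matrix.
MISSING: int = -1

SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "phenotype", "population_label"]


class GenotypeDataError(ValueError):
    """Raised when genotype payload and metadata are inconsistent."""


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric chromosomes sort numerically, others lexicographically after."""
    as_num = pd.to_numeric(chrom, errors="coerce")
    return pd.Series(
        [(0, float(v), "") if not np.isnan(v) else (1, 0.0, str(c))
         for c, v in zip(chrom, as_num)],
        index=chrom.index,
    )


@dataclass
class GenotypeData:
    """Additively coded genotype matrix with SNP and sample metadata.

    Attributes
    ----------
    genotypes:
        ``(n_samples, n_snps)`` int8 array with entries in {0, 1, 2, -1}.
    snps:
        DataFrame with columns ``snp_id, chrom, pos_bp, allele_a, allele_b``,
        sorted by position within each chromosome.
    samples:
        DataFrame with columns ``sample_id, phenotype, population_label``.
        Phenotype is 0 (control), 1 (case) or NaN.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise GenotypeDataError("genotypes must be a 2-D matrix")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise GenotypeDataError(
                f"{n} genotype rows but {len(self.samples)} sample records"
            )
        if len(self.snps) != m:
            raise GenotypeDataError(
                f"{m} genotype columns but {len(self.snps)} SNP records"
            )
        if self.snps["snp_id"].duplicated().any():
            dups = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"]
            raise GenotypeDataError(f"duplicate snp_id: {dups.iloc[0]!r}")
        if self.samples["sample_id"].duplicated().any():
            raise GenotypeDataError("duplicate sample_id")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeDataError("genotype entries must be in {0,1,2,missing}")
        if (self.snps["pos_bp"] < 1).any():
            raise GenotypeDataError("pos_bp must be >= 1 (1-based)")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def is_missing(self) -> np.ndarray:
        return self.genotypes == MISSING

    def take_snps(self, index) -> "GenotypeData":
        index = np.asarray(index)
        return GenotypeData(
            self.genotypes[:, index],
            self.snps.iloc[index],
            self.samples,
        )

    def take_samples(self, index) -> "GenotypeData":
        index = np.asarray(index)
        return GenotypeData(
            self.genotypes[index, :],
            self.snps,
            self.samples.iloc[index],
        )

    def sorted_by_position(self) -> "GenotypeData":
        """Return a copy with SNPs sorted by (chromosome, position)."""
        order = (
            self.snps.assign(_key=_chrom_sort_key(self.snps["chrom"]))
            .sort_values(["_key", "pos_bp"], kind="stable")
            .index.to_numpy()
        )
        return self.take_snps(order)

    def allele_frequency(self) -> np.ndarray:
        """Counted-allele frequency per SNP over non-missing entries."""
        g = self.genotypes.astype(float)
        g[self.genotypes == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)


@dataclass
class StandardizedMatrix:
    """Centered / unit-variance genotype matrix ready for PCA."""

    values: np.ndarray
    snp_means: np.ndarray
    snp_sds: np.ndarray
    snps: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureMatrix:
    """Union of retained single SNPs and haplotype-class count features.

    ``values`` holds per-sample counts in {0,1,2}; ``features`` describes each
    column (``kind`` is ``"snp"`` or ``"hap"``, with locus span and the
    principal component that selected it).
    """

    values: np.ndarray
    features: pd.DataFrame  # feature_id, kind, chrom, start_bp, end_bp, component, n_snps
    sample_ids: pd.Series

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]
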