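"""Quality control, LD-based tag-SNP pruning, imputation and standardization.

The stages run in a fixed order: sample-missingness filter, SNP-missingness
filter (recomputed on retained samples), MAF filter, greedy tag-SNP pruning
(r² against already-retained SNPs within a base-pair window), random
imputation from each SNP's observed genotype distribution, then per-SNP
centering/scaling.  All "above"/"below" thresholds are strict comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING, GenotypeData, StandardizedMatrix

logger = logging.getLogger(__name__)


class PreprocessError(RuntimeError):
    pass


@dataclass
class QcParams:
    """Thresholds for the QC / pruning / imputation stages.

    Defaults: samples with > 3% missing calls and SNPs with > 1% missing
    calls are dropped, SNPs with MAF < 5% are dropped, and a SNP is pruned
    when its r² with a retained SNP within 500 kb exceeds 0.8.
    """

    sample_miss_max: float = 0.03
    snp_miss_max: float = 0.01
    maf_min: float = 0.05
    tag_r2: float = 0.8
    tag_window_bp: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sample_miss_max", "snp_miss_max", "maf_min", "tag_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tag_window_bp < 1:
            raise ValueError("tag_window_bp must be >= 1")


def filter_missingness(g: GenotypeData, p: QcParams) -> GenotypeData:
    """Drop samples, then SNPs, whose missing-call rate is strictly above
    the configured maxima (SNP rates recomputed on retained samples)."""
    miss = g.is_missing()
    sample_rate = miss.mean(axis=1)
    keep_samples = sample_rate <= p.sample_miss_max
    if not keep_samples.any():
        raise PreprocessError("all samples exceed the missingness threshold")
    g = g.take_samples(np.flatnonzero(keep_samples))
    snp_rate = g.is_missing().mean(axis=0)
    keep_snps = snp_rate <= p.snp_miss_max
    if not keep_snps.any():
        raise PreprocessError("all SNPs exceed the missingness threshold")
    g = g.take_snps(np.flatnonzero(keep_snps))
    logger.info(
        "missingness filter: kept %d/%d samples, %d/%d SNPs",
        keep_samples.sum(), keep_samples.size, keep_snps.sum(), keep_snps.size,
    )
    return g


def filter_maf(g: GenotypeData, p: QcParams) -> GenotypeData:
    """Drop SNPs with minor allele frequency strictly below ``maf_min``."""
    maf = g.minor_allele_frequency()
    keep = maf >= p.maf_min
    logger.info("MAF filter: kept %d/%d SNPs", keep.sum(), keep.size)
    return g.take_snps(np.flatnonzero(keep))


def _pairwise_complete_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over entries observed in both vectors."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    xs -= xs.mean()
    ys -= ys.mean()
    denom = (xs @ xs) * (ys @ ys)
    if denom == 0.0:
        return 0.0
    return float((xs @ ys) ** 2 / denom)


def tag_snp_prune(g: GenotypeData, p: QcParams) -> GenotypeData:
    """Greedy left-to-right LD pruning within each chromosome.

    Scanning SNPs in position order, a SNP is dropped when its r² with any
    already-retained SNP within ``tag_window_bp`` exceeds ``tag_r2``
    (strictly).  Deterministic; r² is computed on pairwise-complete additive
    genotypes.
    """
    keep_global: list[int] = []
    for chrom in g.snps["chrom"].unique():
        idx = np.flatnonzero((g.snps["chrom"] == chrom).to_numpy())
        pos = g.snps["pos_bp"].to_numpy()[idx]
        kept: list[int] = []  # local offsets into idx
        for j in range(idx.size):
            drop = False
            for k in reversed(kept):
                if pos[j] - pos[k] > p.tag_window_bp:
                    break
                r2 = _pairwise_complete_r2(
                    g.genotypes[:, idx[j]], g.genotypes[:, idx[k]]
                )
                if r2 > p.tag_r2:
                    drop = True
                    break
            if not drop:
                kept.append(j)
        keep_global.extend(idx[kept])
    keep_global.sort()
    logger.info("tag pruning: kept %d/%d SNPs", len(keep_global), g.n_snps)
    return g.take_snps(keep_global)


def impute_random(g: GenotypeData, p: QcParams) -> GenotypeData:
    """Replace each missing call with a draw from that SNP's observed
    genotype distribution (seeded; non-missing entries untouched)."""
    rng = np.random.default_rng(p.seed)
    geno = g.genotypes.copy()
    miss = geno == MISSING
    for j in np.flatnonzero(miss.any(axis=0)):
        observed = geno[~miss[:, j], j]
        if observed.size == 0:
            raise PreprocessError(
                f"SNP {g.snps['snp_id'].iloc[j]!r} has no observed genotypes"
            )
        counts = np.bincount(observed, minlength=3)[:3]
        draws = rng.choice(3, size=int(miss[:, j].sum()), p=counts / counts.sum())
        geno[miss[:, j], j] = draws.astype(np.int8)
    return GenotypeData(geno, g.snps, g.samples)


def standardize(g: GenotypeData) -> StandardizedMatrix:
    """Center each SNP and scale to unit variance (sd with denominator n-1)."""
    if g.is_missing().any():
        raise PreprocessError("standardize requires a fully imputed matrix")
    x = g.genotypes.astype(np.float64)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    zero = sds == 0.0
    if zero.any():
        bad = g.snps["snp_id"].iloc[int(np.flatnonzero(zero)[0])]
        raise PreprocessError(f"zero-variance SNP {bad!r}; cannot standardize")
    return StandardizedMatrix((x - means) / sds, means, sds, g.snps)


def run_qc(g: GenotypeData, p: QcParams) -> GenotypeData:
    """Missingness -> MAF -> tag pruning -> imputation, in that order."""
    g = filter_missingness(g, p)
    g = filter_maf(g, p)
    g = tag_snp_prune(g, p)
    return impute_random(g, p)
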