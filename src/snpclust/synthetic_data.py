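"""Structured-population genotype simulator with LD blocks and a dense
inversion-like locus.

Independent SNPs follow the Balding–Nichols model: an ancestral allele
frequency p ~ Uniform(0.1, 0.9), per-population frequencies
Beta(p(1-F)/F, (1-p)(1-F)/F) at fixation index F, genotypes Binomial(2, ·).

LD blocks are haplotype-family systems: each block has a small set of founder
haplotypes (families); a sample's two block haplotypes are drawn from the
population-specific family frequencies (themselves Balding–Nichols-diverged
at a per-block family-level F) and copied from the founder with a per-site
mutation rate.  Two of the default blocks are strongly clinal (family-level
F = 0.4), emulating HLA/LCT-like ancestry-informative haplotype systems that
drive the top principal components of real genotype panels; the rest are
weakly differentiated.  The inversion-like locus is a 100-SNP two-family
system whose deeply divergent families are nearly ancestry-independent
(family F = 0.05) — the 8p23-style dense signal the selection step should
isolate.

The binary phenotype is logistic in chosen causal SNP dosages plus an
optional per-population ancestry offset (confounding), with the intercept
solved for a target prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import MISSING, GenotypeData


@dataclass
class BlockSpec:
    """One LD block: founder-haplotype families with within-family mutation."""

    n_snps: int = 50
    n_families: int = 2
    family_fst: float = 0.05
    mutation_rate: float = 0.05


@dataclass
class InversionSpec:
    """Dense two-class locus: two deeply divergent haplotype families."""

    n_snps: int = 100
    family_fst: float = 0.05
    mutation_rate: float = 0.05
    ancestral_freq: float = 0.45  # frequency of family 2
    chrom: str = "8"


@dataclass
class CausalSpec:
    """Where a causal SNP lives and its per-allele odds ratio."""

    location: str  # "independent", "block:<i>", or "inversion"
    odds_ratio: float = 1.5


def default_blocks() -> list[BlockSpec]:
    # family frequencies drift like any other allele: family-level F = genome F
    return [BlockSpec(family_fst=0.05) for _ in range(10)]


def default_causal() -> list[CausalSpec]:
    return [
        CausalSpec("independent", 1.3),
        CausalSpec("independent", 1.4),
        CausalSpec("independent", 1.6),
        CausalSpec("independent", 1.8),
        CausalSpec("inversion", 1.5),
    ]


@dataclass
class SynthConfig:
    n_populations: int = 3
    samples_per_pop: int = 200
    fst: float = 0.05
    n_independent_snps: int = 4000
    block_specs: list = field(default_factory=default_blocks)
    inversion: InversionSpec = field(default_factory=InversionSpec)
    causal_snps: list = field(default_factory=default_causal)
    ancestry_effect: tuple = ()  # per-population log-odds offsets; empty = none
    prevalence: float = 0.5
    missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.ancestry_effect and len(self.ancestry_effect) != self.n_populations:
            raise ValueError("ancestry_effect must have one offset per population")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth retained for validation: family dosages, spans, causals."""

    population: np.ndarray           # per-sample population index
    inversion_dosage: np.ndarray     # per-sample count of family-2 inversion haplotypes
    inversion_span: tuple            # (chrom, start_bp, end_bp)
    block_spans: list                # [(chrom, start_bp, end_bp), ...]
    block_dosage: np.ndarray         # (n, n_blocks) family-2 counts (2-family blocks)
    causal: pd.DataFrame             # snp_id, column, odds_ratio
    complete_genotypes: np.ndarray   # genotypes before missingness masking


@dataclass
class SimulatedData:
    data: GenotypeData
    truth: SimTruth


def _balding_nichols_freqs(p_anc: np.ndarray, fst: float, k: int, rng) -> np.ndarray:
    """Per-population allele frequencies (k x len(p_anc)) under the BN model."""
    if fst < 1e-5:
        return np.tile(p_anc, (k, 1))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return rng.beta(np.tile(a, (k, 1)), np.tile(b, (k, 1)))


def _draw_family_freqs(n_families: int, fst: float, k: int, rng) -> np.ndarray:
    """(k x n_families) per-population haplotype-family frequencies."""
    if n_families == 2:
        anc = rng.uniform(0.3, 0.7)
        f2 = _balding_nichols_freqs(np.array([anc]), fst, k, rng)[:, 0]
        f2 = np.clip(f2, 0.02, 0.98)
        return np.column_stack([1.0 - f2, f2])
    anc = rng.dirichlet(np.full(n_families, 5.0))
    if fst < 1e-5:
        return np.tile(anc, (k, 1))
    conc = anc * (1.0 - fst) / fst
    return rng.dirichlet(conc, size=k)


def _draw_founders(n_families: int, n_snps: int, rng) -> np.ndarray:
    """Founder haplotypes; every site polymorphic across founders.

    With two families the founders are complementary (deep divergence)."""
    if n_families == 2:
        f1 = rng.integers(0, 2, size=n_snps, dtype=np.int8)
        return np.vstack([f1, 1 - f1])
    founders = rng.integers(0, 2, size=(n_families, n_snps), dtype=np.int8)
    mono = np.flatnonzero(founders.min(axis=0) == founders.max(axis=0))
    for j in mono:
        flip = rng.integers(0, n_families)
        founders[flip, j] = 1 - founders[flip, j]
    return founders


def _sample_block(
    founders: np.ndarray,
    family_freqs: np.ndarray,
    population: np.ndarray,
    mutation_rate: float,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two haplotypes per sample; returns (genotypes, family dosage).

    Family dosage is the per-sample count of the last (highest-index) family,
    the "family 2" class for two-family systems."""
    n = population.size
    n_fam, L = founders.shape
    geno = np.zeros((n, L), dtype=np.int8)
    dosage = np.zeros(n, dtype=np.int8)
    for pop in np.unique(population):
        rows = np.flatnonzero(population == pop)
        fams = rng.choice(n_fam, size=(rows.size, 2), p=family_freqs[pop])
        for copy in range(2):
            hap = founders[fams[:, copy]]
            flips = rng.random((rows.size, L)) < mutation_rate
            geno[rows] += np.where(flips, 1 - hap, hap).astype(np.int8)
        dosage[rows] = (fams == n_fam - 1).sum(axis=1).astype(np.int8)
    return geno, dosage


def simulate_populations(config: SynthConfig) -> SimulatedData:
    """Generate the full structured-population genotype dataset.

    Layout: independent SNPs are spread across chromosomes 1..22 with 600 kb
    spacing (outside the default tag-pruning window); each block occupies a
    contiguous 5 kb-spaced run beyond the independent region of its
    chromosome, the inversion a 3 kb-spaced run, with > 1 Mb gaps to any
    neighbour so locus grouping cannot chain unrelated SNPs.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_populations
    n = k * config.samples_per_pop
    population = np.repeat(np.arange(k), config.samples_per_pop)

    columns: list[np.ndarray] = []
    meta: list[tuple] = []

    # --- independent Balding-Nichols SNPs ---------------------------------
    chroms = [str(c) for c in range(1, 23)]
    per_chrom = np.full(22, config.n_independent_snps // 22)
    per_chrom[: config.n_independent_snps % 22] += 1
    indep_geno = np.empty((n, config.n_independent_snps), dtype=np.int8)
    j = 0
    max_indep_pos = 0
    for ci, chrom in enumerate(chroms):
        for local in range(per_chrom[ci]):
            for _ in range(50):  # redraw until the realized MAF clears 5%
                p_anc = rng.uniform(0.1, 0.9)
                freqs = _balding_nichols_freqs(np.array([p_anc]), config.fst, k, rng)[:, 0]
                g = rng.binomial(2, freqs[population]).astype(np.int8)
                f = g.mean() / 2.0
                if 0.05 <= f <= 0.95:
                    break
            indep_geno[:, j] = g
            pos = 1_000_000 + local * 600_000
            meta.append((f"snp_{chrom}_{local}", chrom, pos, "A", "B"))
            max_indep_pos = max(max_indep_pos, pos)
            columns.append(indep_geno[:, j])
            j += 1

    # --- LD blocks ---------------------------------------------------------
    block_spans = []
    block_dosage = np.zeros((n, len(config.block_specs)), dtype=np.int8)
    base_offset = max_indep_pos + 2_000_000
    for b, spec in enumerate(config.block_specs):
        chrom = chroms[b % 22]
        founders = _draw_founders(spec.n_families, spec.n_snps, rng)
        freqs = _draw_family_freqs(spec.n_families, spec.family_fst, k, rng)
        geno, dosage = _sample_block(founders, freqs, population, spec.mutation_rate, rng)
        block_dosage[:, b] = dosage
        start = base_offset + (b // 22) * 3_000_000
        for s in range(spec.n_snps):
            meta.append((f"blk{b}_{s}", chrom, start + s * 5_000, "A", "B"))
            columns.append(geno[:, s])
        block_spans.append((chrom, start, start + (spec.n_snps - 1) * 5_000))

    # --- inversion-like dense locus ----------------------------------------
    inv = config.inversion
    founders = _draw_founders(2, inv.n_snps, rng)
    f2 = np.clip(
        _balding_nichols_freqs(np.array([inv.ancestral_freq]), inv.family_fst, k, rng)[:, 0],
        0.05, 0.95,
    )
    inv_freqs = np.column_stack([1.0 - f2, f2])
    inv_geno, inv_dosage = _sample_block(founders, inv_freqs, population, inv.mutation_rate, rng)
    inv_start = base_offset + 6_000_000
    for s in range(inv.n_snps):
        meta.append((f"inv_{s}", inv.chrom, inv_start + s * 3_000, "A", "B"))
        columns.append(inv_geno[:, s])
    inversion_span = (inv.chrom, inv_start, inv_start + (inv.n_snps - 1) * 3_000)

    genotypes = np.column_stack(columns)
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"])

    # --- causal SNP placement ----------------------------------------------
    causal_rows = []
    indep_pool = rng.permutation(config.n_independent_snps)
    pool_cursor = 0
    for spec in config.causal_snps:
        if spec.location == "independent":
            col = int(indep_pool[pool_cursor])
            pool_cursor += 1
        elif spec.location == "inversion":
            col = config.n_independent_snps + sum(b.n_snps for b in config.block_specs)
            col += int(rng.integers(0, inv.n_snps))
        elif spec.location.startswith("block:"):
            b = int(spec.location.split(":")[1])
            col = config.n_independent_snps + sum(s.n_snps for s in config.block_specs[:b])
            col += int(rng.integers(0, config.block_specs[b].n_snps))
        else:
            raise ValueError(f"unknown causal location {spec.location!r}")
        causal_rows.append((snps["snp_id"].iloc[col], col, spec.odds_ratio))
    causal = pd.DataFrame(causal_rows, columns=["snp_id", "column", "odds_ratio"])

    complete = genotypes.copy()

    # --- missingness masking -----------------------------------------------
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    samples = pd.DataFrame(
        {
            "sample_id": [f"s{idx:04d}" for idx in range(n)],
            "phenotype": np.nan,
            "population_label": [f"pop{p}" for p in population],
        }
    )
    data = GenotypeData(genotypes, snps, samples).sorted_by_position()
    # re-map truth columns after the position sort
    id_to_col = {sid: c for c, sid in enumerate(data.snps["snp_id"])}
    causal["column"] = [id_to_col[sid] for sid in causal["snp_id"]]
    order = [id_to_col[sid] for sid in snps["snp_id"]]
    complete_sorted = np.empty_like(complete)
    complete_sorted[:, order] = complete
    truth = SimTruth(
        population, inv_dosage, inversion_span, block_spans, block_dosage,
        causal, complete_sorted,
    )
    return SimulatedData(data, truth)


def simulate_phenotype(sim: SimulatedData, config: SynthConfig) -> np.ndarray:
    """Bernoulli phenotype: logit P(case) = b0 + Σ log(OR)·g + ancestry offset.

    The intercept is solved numerically so the expected prevalence matches
    ``config.prevalence``.  Uses the complete (pre-masking) genotypes so the
    causal model is exact.  The returned vector is also written into
    ``sim.data.samples['phenotype']``.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = sim.data.n_samples
    eta = np.zeros(n)
    for _, row in sim.truth.causal.iterrows():
        eta += np.log(row["odds_ratio"]) * sim.truth.complete_genotypes[:, int(row["column"])]
    if config.ancestry_effect:
        eta += np.asarray(config.ancestry_effect)[sim.truth.population]

    if not 0.0 < config.prevalence < 1.0:
        raise ValueError(f"target prevalence {config.prevalence} unattainable (must be in (0, 1))")

    def mean_prev(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(eta + b0))))) - config.prevalence

    if mean_prev(-40.0) > 0 or mean_prev(40.0) < 0:
        raise ValueError(f"target prevalence {config.prevalence} unattainable")
    b0 = brentq(mean_prev, -40.0, 40.0)
    phenotype = (rng.random(n) < 1.0 / (1.0 + np.exp(-(eta + b0)))).astype(float)
    sim.data.samples["phenotype"] = phenotype
    return phenotype


def hudson_fst(g: GenotypeData, population: np.ndarray) -> float:
    """Hudson's Fst estimator (ratio of averages) over all SNP pairs of
    populations; used to validate the generator's divergence."""
    geno = g.genotypes.astype(float)
    geno[g.genotypes == MISSING] = np.nan
    pops = np.unique(population)
    nums, dens = [], []
    for i in range(len(pops)):
        for jj in range(i + 1, len(pops)):
            gi = geno[population == pops[i]]
            gj = geno[population == pops[jj]]
            p1 = np.nanmean(gi, axis=0) / 2.0
            p2 = np.nanmean(gj, axis=0) / 2.0
            n1 = np.sum(~np.isnan(gi), axis=0) * 2
            n2 = np.sum(~np.isnan(gj), axis=0) * 2
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            nums.append(np.nansum(num))
            dens.append(np.nansum(den))
    return float(np.sum(nums) / np.sum(dens))
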