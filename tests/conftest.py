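import numpy as np
import pandas as pd
import pytest

import snpclust as sc
from snpclust.pipeline import RunConfig, run_pipeline


def make_genotype_data(genotypes, chrom=None, pos=None, phenotype=None, labels=None):
    """Small GenotypeData builder for unit tests."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else list(range(1, m + 1))
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(m)],
            "chrom": [str(c) for c in chrom],
            "pos_bp": pos,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "phenotype": phenotype if phenotype is not None else np.nan,
            "population_label": labels if labels is not None else [None] * n,
        }
    )
    return sc.GenotypeData(genotypes, snps, samples)


@pytest.fixture(scope="session")
def scene_runs():
    """Lazily cached default-scene pipeline runs keyed by seed."""
    cache = {}

    def run(seed: int):
        if seed not in cache:
            cfg = RunConfig(
                simulate=sc.SynthConfig(),
                n_components=12,
                seed=seed,
                out_dir=f"scratch/test_scene_{seed}",
            )
            cache[seed] = run_pipeline(cfg, write_artifacts=False)
        return cache[seed]

    return run


def inversion_hap_feature(result):
    """(counts, truth dosage) for the haplotype feature covering the planted
    inversion locus, or (None, None) if absent."""
    sim = result.simulated
    chrom, start, end = sim.truth.inversion_span
    feats = result.features
    for i in feats.features.index:
        row = feats.features.loc[i]
        if (
            row["kind"] == "hap"
            and str(row["chrom"]) == str(chrom)
            and row["start_bp"] >= start
            and row["end_bp"] <= end
        ):
            return feats.values[:, i], sim.truth.inversion_dosage
    return None, None
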