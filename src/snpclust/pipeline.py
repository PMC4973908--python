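"""End-to-end pipeline: input -> QC -> PCA -> contributor selection ->
haplotype summarization -> re-PCA -> optional association benchmark.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed, spawn_key=(stage,))`` so each stage
is independently reproducible.  Every artifact is a TSV; a JSON manifest
records versions, seeds, per-stage entity counts and the before/after
ancestry-signal diagnostic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association_benchmark import (
    AssocResult,
    add_fdr,
    assoc_glm,
    benchmark_table,
    eigenstrat_assoc,
    genomic_control,
)
from .contributor_selection import SelectionParams, select_strong_contributors
from .datatypes import FeatureMatrix, GenotypeData
from .genotype_io import attach_sample_table, read_plink, read_vcf, write_feature_table
from .haplotype_summarization import SummarizationParams, build_feature_matrix
from .pca_engine import pc_label_association, run_pca
from .preprocess import QcParams, run_qc, standardize
from .synthetic_data import (
    BlockSpec,
    CausalSpec,
    InversionSpec,
    SimulatedData,
    SynthConfig,
    simulate_phenotype,
    simulate_populations,
)

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "impute", "selection", "summarize", "benchmark")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence(global_seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    plink_prefix: str | None = None
    vcf_path: str | None = None
    simulate: SynthConfig | None = None
    sample_table: str | None = None
    qc: QcParams = field(default_factory=QcParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    summarization: SummarizationParams = field(default_factory=SummarizationParams)
    n_components: int = 100
    ancestry_n_pcs: int = 5
    benchmark_methods: tuple = ()  # subset of raw/gc/eigenstrat-5/eigenstrat-10/snpclust
    out_dir: str = "snpclust_run"
    seed: int = 0

    def __post_init__(self) -> None:
        sources = sum(x is not None for x in (self.plink_prefix, self.vcf_path, self.simulate))
        if sources != 1:
            raise ValueError("exactly one input source (plink, vcf, simulate) is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            blocks = [BlockSpec(**b) for b in sim.pop("block_specs", [])] or None
            inversion = sim.pop("inversion", None)
            causal = [CausalSpec(**c) for c in sim.pop("causal_snps", [])] or None
            sim = SynthConfig(
                **sim,
                **({"block_specs": blocks} if blocks else {}),
                **({"inversion": InversionSpec(**inversion)} if inversion else {}),
                **({"causal_snps": causal} if causal else {}),
            )
        kwargs = dict(raw)
        if "qc" in kwargs:
            kwargs["qc"] = QcParams(**kwargs["qc"])
        if "selection" in kwargs:
            kwargs["selection"] = SelectionParams(**kwargs["selection"])
        if "summarization" in kwargs:
            kwargs["summarization"] = SummarizationParams(**kwargs["summarization"])
        if "benchmark_methods" in kwargs:
            kwargs["benchmark_methods"] = tuple(kwargs["benchmark_methods"])
        return cls(simulate=sim, **kwargs)


@dataclass
class PipelineResult:
    genotypes: GenotypeData           # QC'd + imputed analysis data
    features: FeatureMatrix
    manifest: dict
    before_r2: np.ndarray
    after_r2: np.ndarray
    assoc: dict                       # method -> AssocResult
    selection: object = None          # SelectionResult
    simulated: SimulatedData | None = None


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_input(config: RunConfig) -> tuple[GenotypeData, SimulatedData | None]:
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=stage_seed(config.seed, "simulate"))
        sim = simulate_populations(sim_cfg)
        simulate_phenotype(sim, sim_cfg)
        g = sim.data
    elif config.plink_prefix is not None:
        g, sim = read_plink(config.plink_prefix), None
    else:
        g, sim = read_vcf(config.vcf_path), None
    if config.sample_table:
        g = attach_sample_table(g, config.sample_table)
    return g, sim


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> PipelineResult:
    """Execute every stage and (optionally) write the artifact set."""
    out = Path(config.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "counts": {},
    }

    g_raw, sim = load_input(config)
    manifest["counts"]["input"] = {"samples": g_raw.n_samples, "snps": g_raw.n_snps}

    qc = dataclasses.replace(config.qc, seed=stage_seed(config.seed, "impute"))
    g = run_qc(g_raw, qc)
    manifest["counts"]["qc"] = {"samples": g.n_samples, "snps": g.n_snps}

    x = standardize(g)
    n_comp = min(config.n_components, g.n_samples - 1, g.n_snps)
    pca = run_pca(x, n_components=n_comp)
    manifest["counts"]["pca_components"] = n_comp

    labels = g.samples["population_label"]
    before_r2 = np.array([])
    if labels.notna().sum() and labels.dropna().nunique() >= 2:
        before = pc_label_association(pca, labels, n_pcs=config.ancestry_n_pcs)
        before_r2 = before.r_squared
        manifest["ancestry_r2_before"] = [float(v) for v in before_r2]

    sel_params = dataclasses.replace(config.selection, seed=stage_seed(config.seed, "selection"))
    selection = select_strong_contributors(pca, sel_params)
    manifest["counts"]["selected_snps_union"] = int(selection.selected_union().size)

    summ = dataclasses.replace(config.summarization, seed=stage_seed(config.seed, "summarize"))
    features = build_feature_matrix(g, selection, summ)
    manifest["counts"]["features"] = {
        "snp": int((features.features["kind"] == "snp").sum()),
        "hap": int((features.features["kind"] == "hap").sum()),
    }

    # re-PCA on the feature matrix (zero-variance features excluded)
    after_r2 = np.array([])
    fvals = features.values.astype(float)
    keep = fvals.std(axis=0) > 0
    if keep.sum() >= 2 and before_r2.size:
        feat_g = GenotypeData(
            features.values[:, keep],
            pd.DataFrame(
                {
                    "snp_id": features.features["feature_id"][keep],
                    "chrom": features.features["chrom"][keep].fillna("0"),
                    "pos_bp": features.features["start_bp"][keep].fillna(1).astype(int),
                    "allele_a": "A",
                    "allele_b": "B",
                }
            ),
            g.samples,
        )
        x2 = standardize(feat_g)
        n2 = min(config.ancestry_n_pcs, x2.n_samples - 1, x2.n_snps)
        pca2 = run_pca(x2, n_components=n2)
        after = pc_label_association(pca2, labels, n_pcs=n2)
        after_r2 = after.r_squared
        manifest["ancestry_r2_after"] = [float(v) for v in after_r2]
    if before_r2.size and after_r2.size:
        b, a = float(before_r2.mean()), float(after_r2.mean())
        manifest["ancestry_r2_mean_before"] = b
        manifest["ancestry_r2_mean_after"] = a
        manifest["ancestry_r2_reduction"] = (b - a) / b if b > 0 else np.nan

    # optional association benchmark
    assoc: dict[str, AssocResult] = {}
    pheno = g.samples["phenotype"].to_numpy(dtype=float)
    if config.benchmark_methods and np.unique(pheno[~np.isnan(pheno)]).size == 2:
        geno_f = g.genotypes.astype(float)
        ids = g.snps["snp_id"].tolist()
        if "raw" in config.benchmark_methods or "gc" in config.benchmark_methods:
            raw = add_fdr(assoc_glm(geno_f, pheno, feature_ids=ids, method="raw"))
            if "raw" in config.benchmark_methods:
                assoc["raw"] = raw
            if "gc" in config.benchmark_methods:
                assoc["gc"] = add_fdr(genomic_control(raw))
        for method in config.benchmark_methods:
            if method.startswith("eigenstrat-"):
                n_pcs = int(method.split("-")[1])
                assoc[method] = add_fdr(eigenstrat_assoc(g, pheno, n_pcs=n_pcs))
        if "snpclust" in config.benchmark_methods:
            assoc["snpclust"] = add_fdr(
                assoc_glm(
                    fvals[:, keep],
                    pheno,
                    feature_ids=features.features["feature_id"][keep].tolist(),
                    method="snpclust",
                )
            )
        manifest["lambda_gc"] = assoc.get("gc").lambda_gc if "gc" in assoc else None

    if write_artifacts:
        _write_tsv(
            pd.DataFrame(pca.scores, columns=[f"PC{i+1}" for i in range(n_comp)]).assign(
                sample_id=g.samples["sample_id"]
            ),
            out / "scores.tsv",
        )
        _write_tsv(selection.to_frame(), out / "selection_report.tsv")
        _write_tsv(features.features, out / "feature_report.tsv")
        write_feature_table(features, out / "features.tsv")
        for method, res in assoc.items():
            _write_tsv(res.table, out / f"assoc_{method}.tsv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(g, features, manifest, before_r2, after_r2, assoc, selection, sim)


def feature_positions(g: GenotypeData, features: FeatureMatrix) -> dict[str, pd.DataFrame]:
    """Position tables for benchmark_table: one for SNP-level methods, one
    for the summarized feature set."""
    snp_pos = pd.DataFrame(
        {
            "feature_id": g.snps["snp_id"],
            "chrom": g.snps["chrom"],
            "start_bp": g.snps["pos_bp"],
            "end_bp": g.snps["pos_bp"],
        }
    )
    feat_pos = features.features[["feature_id", "chrom", "start_bp", "end_bp"]].copy()
    # leftover SNP features inherit their SNP position
    missing = feat_pos["start_bp"].isna()
    if missing.any():
        lookup = snp_pos.set_index("feature_id")
        for i in feat_pos.index[missing]:
            fid = feat_pos.at[i, "feature_id"]
            if fid in lookup.index:
                feat_pos.loc[i, ["chrom", "start_bp", "end_bp"]] = lookup.loc[
                    fid, ["chrom", "start_bp", "end_bp"]
                ].to_numpy()
    return {"snp": snp_pos, "feature": feat_pos}
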