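"""Compare association strategies on an ancestry-confounded case/control panel.

Case prevalence differs by population, so the naive GWAS is inflated
(lambda >> 1).  Genomic control rescales the statistics; Eigenstrat puts
ancestry PCs in the model; the summarized feature set is tested directly.
The planted dense locus stands in for a dominant real locus, and the causal
SNP sits inside an ordinary LD block outside it.
"""

import snpclust as sc
from snpclust.association_benchmark import add_fdr, benchmark_table
from snpclust.pipeline import RunConfig, feature_positions, run_pipeline

scene = sc.SynthConfig(
    causal_snps=[sc.CausalSpec("block:0", 1.8)],
    ancestry_effect=(0.0, 0.5, 1.0),
)
cfg = RunConfig(
    simulate=scene,
    n_components=12,
    seed=11,
    out_dir="scratch/example_bench",
    benchmark_methods=("raw", "gc", "eigenstrat-5", "snpclust"),
)
result = run_pipeline(cfg, write_artifacts=False)
print(f"genomic-control inflation factor lambda = {result.assoc['gc'].lambda_gc:.2f}")

positions = feature_positions(result.genotypes, result.features)
pos_map = {m: (positions["feature"] if m == "snpclust" else positions["snp"])
           for m in result.assoc}
table = benchmark_table(result.assoc, pos_map, [result.simulated.truth.inversion_span])
print(table.to_string(index=False))
print("n_q_outside_locus counts significant (q < 0.05) features outside the")
print("planted dense locus: the summarized feature set concentrates its few")
print("tests on real loci instead of thousands of confounded SNPs.")
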