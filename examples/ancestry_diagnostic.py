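"""Quantify how strongly the top principal components encode ancestry.

Genome-wide PCA of a structured panel puts the population signal on the
first components; the per-PC one-way ANOVA R-squared against population
labels makes that visible as a number instead of a scatter plot.
"""

import numpy as np

import snpclust as sc

cfg = sc.SynthConfig(samples_per_pop=150, n_independent_snps=2000, seed=7)
sim = sc.simulate_populations(cfg)
g = sc.run_qc(sim.data, sc.QcParams(seed=0))
x = sc.standardize(g)
pca = sc.run_pca(x, n_components=10)

print("explained variance fraction:", np.round(pca.explained_var_fraction[:5], 4))
assoc = sc.pc_label_association(pca, g.samples["population_label"], n_pcs=5)
for c, (r2, p) in enumerate(zip(assoc.r_squared, assoc.p_value), start=1):
    print(f"PC{c}: population R^2 = {r2:.3f}  (ANOVA p = {p:.2e})")
print("PC1/PC2 carry nearly all of the between-population variance —")
print("with K discrete populations there are only K-1 ancestry axes, so later")
print("PCs are ancestry-free even before any correction is applied.")
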