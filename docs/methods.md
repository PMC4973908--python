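# Methods

`snpclust` reduces the ancestry signal that dominates genome-wide SNP
clustering.  Naive PCA or clustering of a case/control genotype matrix
groups samples by geographic origin first, because small allele-frequency
differences between subpopulations accumulate over hundreds of thousands of
markers.  The package keeps the *localized* sources of genetic variation —
dense, correlated SNP groups such as large LD blocks and inversion
polymorphisms — and discards the diffuse genome-wide ancestry axes, then
compresses each retained locus into a single haplotype-class count so that
one locus contributes one feature instead of hundreds of correlated SNPs.

## Pipeline

1. **QC / analysis set.**  Samples with a missing-call rate strictly above
   3% are removed, then SNPs strictly above 1% (recomputed on the retained
   samples — the only self-consistent order), then SNPs with MAF strictly
   below 5%.  Redundant SNPs are pruned by a deterministic greedy
   left-to-right scan per chromosome: a SNP is dropped when its squared
   Pearson correlation with any already-retained SNP within 500 kb
   (inclusive window, 1-based positions) strictly exceeds 0.8; r² is
   computed on pairwise-complete additive genotypes, because pruning runs
   before imputation.  Remaining missing calls are imputed by sampling from
   each SNP's observed genotype distribution (seeded), and each SNP is
   centered and scaled to unit variance (sd with denominator n−1; a
   zero-variance column is a hard error).

2. **PCA.**  Exact SVD of the standardized sample × SNP matrix.  Scores are
   `X·V`, loadings `V` are orthonormal, and the explained-variance fraction
   of component *c* is its eigenvalue over the number of SNPs (the total
   variance of a unit-variance matrix).  Column signs are fixed so that each
   loading column's largest-magnitude entry is positive, making runs
   bit-reproducible.  The default number of components is 100, sized for
   panels of several thousand samples (roughly the top 2% of possible
   components); the test and acceptance scenes apply the same 2% rule to
   their 600 samples and use 12, which also covers the scenes' full
   structured spectrum (two ancestry axes, ten blocks, one inversion).

3. **Contributor selection.**  Per component, the 3,000 largest absolute
   loadings are kept and a k-component Gaussian mixture (k starting at 2) is
   fitted to them by EM (scikit-learn; k-means++ initialization, 5 restarts,
   fixed seed, variance floor 1e−12 with a warning).  SNPs assigned to the
   highest-mean mixture component with classification uncertainty
   `1 − max_k posterior` below 1e−6 are selected.  If the selection spans
   more than 8 chromosomes — the signature of a diffuse axis — k is
   increased up to 5; failing that, the component selects nothing.  Two
   genuinely open choices are resolved as package defaults and exposed as
   switches: only the *highest-mean* component counts as "strong" (with
   k > 2 low-loading points can also reach zero uncertainty, and top-only
   selection shrinks as k grows, which the escalation loop presupposes), and
   the chromosome condition is evaluated per component independently.

4. **Haplotype summarization.**  Per component, selected SNPs on one
   chromosome with consecutive gaps strictly below 1 Mb chain into loci
   (singletons stay as single-SNP features).  Each locus is phased by a
   partition–ligation EM:

   * within disjoint windows of ≤ 8 SNPs, haplotype frequencies are
     estimated by plain EM over every compatible phasing of every sample
     (2^(h−1) unordered pairs for h heterozygous sites), so loci that fit in
     one window get the exact exhaustive-EM answer;
   * adjacent segments are merged hierarchically.  Candidate haplotypes for
     the merged segment are concatenations of each sample's top window pairs
     (posterior ≥ 0.01, at most 8 per side, both orientations).  The merge
     EM uses a mutation-tolerant emission: an observed candidate is a *pool*
     haplotype (the ≤ 64 most plausible candidates) copied with independent
     per-site errors at rate 0.03, i.e. `P(obs j) = Σ_i f_i (ε/(1−ε))^{d_ij}`
     up to a constant.  Exact string matching fails on long segments —
     nearly every concatenated haplotype is unique once haplotypes carry
     private mutations, which leaves the two orientations of a
     doubly-heterozygous sample unresolved and produces switch chimeras;
     the copying kernel restores frequency sharing (measured on a 95-SNP
     two-family locus: chimera rate 36% → 0, class fidelity 0.58 → 1.00).
     Runtime stays linear in locus length at fixed window size.
   * every sample is assigned its maximum-posterior pair; pairs sum to the
     genotype at every site by construction (hard assertion).

   The 2n inferred haplotypes are projected on their own first principal
   component and a 2-component Gaussian mixture assigns each haplotype to a
   class (the projection choice matches how such loci separate visually;
   k-modes on raw binary vectors would be the alternative).  Class 1 is the
   more frequent class; a tie goes to the class containing the
   lexicographically smallest haplotype.  The locus becomes one per-sample
   count in {0,1,2} of class-2 haplotypes.  Haplotype features on the same
   chromosome with r² strictly above 0.8 are pruned, keeping the earlier
   feature in (component, position) order; zero-variance features are
   dropped with a warning.  A locus whose haplotypes are all identical is
   demoted back to single SNPs rather than aborting the run.  Leftover
   single SNPs selected by several components are emitted once.

5. **Association benchmark.**  Each feature (SNP dosage or haplotype count)
   is tested in a binomial GLM with logit link; the statistic is the 1-df
   likelihood-ratio test of (covariates + feature) against (covariates
   only), which for a single added term is what a Type-2 analysis of
   deviance computes.  Multiple testing uses Benjamini–Hochberg q-values.
   Genomic control divides every χ² by λ = median(χ²)/median(χ²₁)
   (the reference median ≈ 0.455 is always computed from `scipy.stats.chi2`,
   never hard-coded), with λ floored at 1 so correction never inflates.
   Eigenstrat-style correction enters the first k genotype PCs (k = 5 or 10)
   as GLM covariates — the PC-covariate logistic variant rather than the
   original Armitage-residual formulation, an equivalent-in-spirit but
   simpler contract.  Perfect separation or non-convergence falls back to
   Firth's penalized likelihood (Jeffreys prior, penalized LRT) and flags
   the feature.  The per-feature fits use an in-module damped Newton/IRLS
   solver; the test suite cross-checks its log-likelihoods against
   statsmodels GLM and a grid-search oracle to 1e−6.

6. **Ancestry diagnostic.**  For each of the first n PCs, one-way ANOVA of
   the score vector on a categorical sample label: R² = between-group SS /
   total SS, p from the F distribution.  Samples with missing labels are
   excluded; label levels with fewer than two samples are dropped with a
   warning.  Note a structural bound used when interpreting this diagnostic:
   centered PC score vectors are mutually orthogonal, so the R² values of
   all components against a K-level label sum to at most K−1.  With three
   discrete populations the mean R² over the first five PCs therefore cannot
   exceed 0.4 for any data; the two ancestry axes carry ≈ 0.93 each on the
   default scene and every later PC is ancestry-free.  The meaningful
   summary is the *relative* drop after summarization, not the absolute
   level.

## Synthetic data

The generator produces the structure the method assumes, with ground truth
retained for validation:

* **Independent SNPs** follow the Balding–Nichols model: ancestral frequency
  p ~ U(0.1, 0.9), population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) at
  F = 0.05, genotypes Binomial(2, ·); a SNP is redrawn until its realized
  MAF clears 5% so the MAF filter is exercised only by constructed
  violations.
* **LD blocks** (default ten of 50 SNPs) are two-family haplotype systems:
  complementary founder haplotypes, per-population family frequencies drawn
  by the same Balding–Nichols law at family-level F = 0.05 (haplotype
  families drift like alleles), and per-site within-family mutation at 0.05.
  That mutation rate puts within-block r² near 0.65 — strong LD, yet below
  the 0.8 pruning threshold, as in real tag-SNP-pruned panels where dense
  loci persist.
* **The inversion-like locus** is a 100-SNP two-family system with deeply
  divergent founders and near-ancestry-independent family frequencies
  (ancestral family-2 frequency 0.45, family F = 0.05) — a dense, localized,
  ancestry-free signal the selection stage should isolate on its own
  component, emulating large polymorphic inversions.
* **Phenotype**: logit P(case) = b₀ + Σ log(OR)·g + ancestry offset per
  population, with b₀ solved by Brent's method for a target prevalence of
  0.5 and Bernoulli draws from a seeded generator.  Defaults plant five
  causal SNPs (OR 1.3–1.8), one inside the inversion; the ancestry offset is
  zero unless a confounded scene sets it.  Missing calls are masked at rate
  0.002.

What the generator does **not** emulate: recombination-map LD decay,
admixture gradients and clines (populations are discrete), genotyping batch
artifacts, rare variants, and chromosome X.  Passing tests therefore show
that the machinery behaves as designed under the stated model, not that any
particular real panel will show the same effect sizes; in particular real
European labels are many-leveled and gradient-like, where the per-PC
ancestry R² behaves differently from the discrete three-population cap
described above.

## Numerical choices and degenerate inputs

* All randomness flows from explicit seeds; the pipeline derives per-stage
  seeds from the global seed via `SeedSequence(seed, spawn_key=(stage,))`,
  so stages are independently reproducible and artifacts are bit-identical
  across reruns (asserted in the tests).
* Mixture EM: scikit-learn spherical 1-D mixtures, reg_covar 1e−12,
  max_iter 500; identical input values trigger a degeneracy warning.
* Phasing EM: window EM tolerance 1e−7 (max 300 iterations), ligation EM
  1e−6 (max 200); non-convergence keeps the best likelihood and warns —
  expected on structureless loci.
* Association: Newton steps are damped to a max-norm of 10; |β| > 25 at
  convergence is treated as separation and rerouted to Firth.
* TSVs are written with a fixed float format (`%.10g`) so text artifacts
  are byte-stable.

## Problem sizes

The default test scene is 3 populations × 200 samples and ≈ 4,600 SNPs
(4,000 independent + 10×50 block + 100 inversion); calibration scenes use
1,000 samples × ≈ 5,000 null SNPs.  These sizes give the acceptance checks
stable statistics (binomial s.e. of a 5% rate at 5,000 tests ≈ 0.3%) while a
full pipeline run stays under a minute.
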