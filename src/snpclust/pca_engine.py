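"""PCA of the standardized genotype matrix and an ancestry-signal diagnostic.

The diagnostic (:func:`pc_label_association`) quantifies how strongly each
principal component separates categorical sample labels (countries, centers,
populations) via one-way ANOVA: R² = between-group SS / total SS with an
F-test p-value.  Naive genome-wide PCA typically shows high R² on the first
components; after contributor selection and haplotype summarization the
signal should drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import StandardizedMatrix


@dataclass
class PCAResult:
    """Scores (samples x C), orthonormal loadings (SNPs x C), and the
    fraction of total variance explained by each component."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_var_fraction: np.ndarray
    snps: pd.DataFrame


@dataclass
class PcLabelAssociation:
    """Per-component one-way ANOVA of PC scores on a categorical label."""

    r_squared: np.ndarray
    p_value: np.ndarray

    def mean_r2(self, k: int | None = None) -> float:
        r = self.r_squared if k is None else self.r_squared[:k]
        return float(np.mean(r))


def run_pca(x: StandardizedMatrix, n_components: int = 100) -> PCAResult:
    """Exact PCA by SVD of the standardized sample x SNP matrix.

    ``scores = X @ loadings``; the explained-variance fraction of component c
    is its eigenvalue over the total variance (= n_snps for a unit-variance
    matrix).  Column signs are fixed so each loading column's
    largest-magnitude entry is positive, making results reproducible.
    """
    n, m = x.values.shape
    if n_components > min(n, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_snps)={min(n, m)}"
        )
    u, s, vt = np.linalg.svd(x.values, full_matrices=False)
    loadings = vt[:n_components].T
    # sign convention: largest-|entry| of each loading column is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    eigenvalues = s[:n_components] ** 2 / (n - 1)
    scores = x.values @ loadings
    return PCAResult(scores, loadings, eigenvalues / m, x.snps)


def explained_variance_fraction(r: PCAResult, k: int) -> float:
    """Total variance fraction explained by the first ``k`` components."""
    if k > r.explained_var_fraction.size:
        raise ValueError(f"k={k} exceeds the {r.explained_var_fraction.size} computed components")
    return float(r.explained_var_fraction[:k].sum())


def _anova_r2(score: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = score.size
    grand = score.mean()
    ss_total = float(((score - grand) ** 2).sum())
    if ss_total == 0.0:
        return 0.0, 1.0
    ss_between = 0.0
    for level in range(n_groups):
        sub = score[codes == level]
        ss_between += sub.size * (sub.mean() - grand) ** 2
    r2 = ss_between / ss_total
    df1 = n_groups - 1
    df2 = n - n_groups
    if df2 <= 0:
        return r2, np.nan
    f = (ss_between / df1) / max(ss_total - ss_between, 1e-300) * df2
    return r2, float(stats.f.sf(f, df1, df2))


def pc_label_association(
    r: PCAResult, labels, n_pcs: int | None = None
) -> PcLabelAssociation:
    """One-way ANOVA of each of the first ``n_pcs`` score vectors on a
    categorical label (samples with missing labels excluded; levels with
    fewer than 2 samples dropped with a warning)."""
    labels = pd.Series(labels).reset_index(drop=True)
    if n_pcs is None:
        n_pcs = r.scores.shape[1]
    n_pcs = min(n_pcs, r.scores.shape[1])
    ok = labels.notna().to_numpy()
    labels = labels[ok]
    counts = labels.value_counts()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(f"dropping label level(s) with < 2 samples: {list(small)}")
        keep = ~labels.isin(small)
        ok[ok] = keep.to_numpy()
        labels = labels[keep]
    codes, levels = pd.factorize(labels)
    if len(levels) < 2:
        raise ValueError("pc_label_association needs >= 2 label levels")
    scores = r.scores[ok]
    r2 = np.empty(n_pcs)
    p = np.empty(n_pcs)
    for c in range(n_pcs):
        r2[c], p[c] = _anova_r2(scores[:, c], codes, len(levels))
    return PcLabelAssociation(r2, p)
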