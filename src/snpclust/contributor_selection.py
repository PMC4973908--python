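"""Per-component selection of strong SNP contributors.

For each principal component, a Gaussian mixture is fitted to the absolute
values of the component's top SNP loadings.  SNPs classified with (near)
zero uncertainty into the highest-mean mixture component are "strong
contributors".  If the selection spans more than ``max_chroms`` chromosomes
— the signature of a diffuse, ancestry-like axis rather than a localized
locus — the mixture is refitted with one more component, up to
``mixtures_max``; failing that, the component contributes no SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gmm import GmmFit, fit_gmm_1d
from .pca_engine import PCAResult


@dataclass
class SelectionParams:
    n_top: int = 3000
    max_chroms: int = 8
    mixtures_min: int = 2
    mixtures_max: int = 5
    uncertainty_tol: float = 1e-6
    #: select only from the highest-mean mixture component (see docs); when
    #: False, every non-bottom component is eligible.
    top_component_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mixtures_min > self.mixtures_max:
            raise ValueError("mixtures_min must be <= mixtures_max")
        if self.n_top < self.mixtures_max:
            raise ValueError("n_top must be >= mixtures_max")


@dataclass
class ComponentSelection:
    component: int
    snp_indices: np.ndarray          # indices into the PCA's SNP table
    n_mixtures_used: int | None      # None when no k satisfied the condition
    uncertainties: np.ndarray        # per selected SNP

    @property
    def n_selected(self) -> int:
        return self.snp_indices.size


@dataclass
class SelectionResult:
    per_component: list[ComponentSelection]
    snps: pd.DataFrame

    def selected_union(self) -> np.ndarray:
        """Unique selected SNP indices across all components."""
        if not self.per_component:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate([c.snp_indices for c in self.per_component]))

    def to_frame(self) -> pd.DataFrame:
        """Per-component report: k used, selection size, chromosomes spanned."""
        rows = []
        for c in self.per_component:
            chroms = self.snps["chrom"].iloc[c.snp_indices].nunique()
            rows.append((c.component, c.n_mixtures_used, c.n_selected, chroms))
        return pd.DataFrame(rows, columns=["component", "n_mixtures", "n_selected", "n_chromosomes"])


def fit_abs_loading_gmm(values: np.ndarray, k: int, seed: int) -> GmmFit:
    """EM fit of a k-component Gaussian mixture to non-negative loadings."""
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("absolute loadings must be non-negative")
    return fit_gmm_1d(values, k, seed)


def classification_uncertainty(fit: GmmFit) -> np.ndarray:
    """1 - max posterior per point; 0 = certain, bounded by 1 - 1/k."""
    return 1.0 - fit.posteriors.max(axis=1)


def select_strong_contributors(r: PCAResult, params: SelectionParams) -> SelectionResult:
    """Apply the mixture-based selection to every computed component."""
    chrom = r.snps["chrom"].to_numpy()
    n_components = r.loadings.shape[1]
    out: list[ComponentSelection] = []
    for c in range(n_components):
        abs_load = np.abs(r.loadings[:, c])
        n_top = min(params.n_top, abs_load.size)
        top_idx = np.argpartition(abs_load, -n_top)[-n_top:]
        top_idx = top_idx[np.argsort(abs_load[top_idx], kind="stable")]
        values = abs_load[top_idx]
        chosen_idx = np.empty(0, dtype=int)
        chosen_unc = np.empty(0)
        k_used: int | None = None
        for k in range(params.mixtures_min, params.mixtures_max + 1):
            fit = fit_abs_loading_gmm(values, k, params.seed)
            unc = classification_uncertainty(fit)
            assigned = fit.posteriors.argmax(axis=1)
            if params.top_component_only:
                in_strong = assigned == k - 1
            else:
                in_strong = assigned >= 1
            sel = in_strong & (unc < params.uncertainty_tol)
            n_chrom = len(np.unique(chrom[top_idx[sel]]))
            if n_chrom <= params.max_chroms:
                chosen_idx = top_idx[sel]
                chosen_unc = unc[sel]
                k_used = k
                break
        order = np.argsort(chosen_idx)
        out.append(
            ComponentSelection(c, chosen_idx[order], k_used, chosen_unc[order])
        )
    return SelectionResult(out, r.snps)
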