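"""Thin wrapper around scikit-learn's 1-D Gaussian mixture EM.

Components are always reported sorted by ascending mean so callers can refer
to "the highest-mean component" stably.  Degenerate components (variance
collapsing onto repeated values) are floored at 1e-12 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

VAR_FLOOR = 1e-12


@dataclass
class GmmFit:
    means: np.ndarray        # (k,) ascending
    variances: np.ndarray    # (k,)
    weights: np.ndarray      # (k,), sums to 1
    posteriors: np.ndarray   # (n, k), rows sum to 1

    @property
    def n_components(self) -> int:
        return self.means.size


def fit_gmm_1d(values: np.ndarray, k: int, seed: int, n_init: int = 5) -> GmmFit:
    """Fit a k-component 1-D Gaussian mixture by EM.

    k-means++ initialization with a fixed seed, ``n_init`` restarts keeping
    the best log-likelihood.
    """
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    if values.shape[0] <= k:
        raise ValueError(f"need more than {k} values to fit {k} components")
    if np.ptp(values) == 0.0:
        warnings.warn("all values identical; mixture fit is degenerate")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="spherical",
        reg_covar=VAR_FLOOR,
        n_init=n_init,
        init_params="k-means++",
        max_iter=500,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn convergence chatter on degenerate inputs
        gm.fit(values)
    order = np.argsort(gm.means_.ravel(), kind="stable")
    means = gm.means_.ravel()[order]
    variances = gm.covariances_.ravel()[order]
    if (variances <= VAR_FLOOR).any():
        warnings.warn("mixture component variance at floor (1e-12); degenerate fit")
        variances = np.maximum(variances, VAR_FLOOR)
    weights = gm.weights_[order]
    posteriors = gm.predict_proba(values)[:, order]
    return GmmFit(means, variances, weights, posteriors)
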