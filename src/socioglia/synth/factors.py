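"""Latent-factor generative model for morphology feature matrices.

Used to exercise the factor-analysis stage with known ground truth:
observed features are ``x = L f + e`` with orthogonal standard-normal
factors ``f``, a fixed loading pattern ``L`` and independent Gaussian
noise. The default pattern has three factors loading 0.8 on disjoint
blocks of the 13 features, giving block correlations of 0.64 and exactly
three correlation-matrix eigenvalues above 1 in the population.
"""

from __future__ import annotations

import numpy as np

__all__ = ["default_loadings", "gen_factor_features"]


def default_loadings(n_features: int = 13, n_factors: int = 3,
                     loading: float = 0.8) -> np.ndarray:
    """Block loading matrix: factors own disjoint runs of features."""
    L = np.zeros((n_features, n_factors))
    bounds = np.linspace(0, n_features, n_factors + 1).astype(int)
    for k in range(n_factors):
        L[bounds[k]:bounds[k + 1], k] = loading
    return L


def gen_factor_features(n_samples: int = 500, loadings: np.ndarray | None = None,
                        noise_sd: float = 0.6, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, factor_scores) from the linear factor model."""
    L = default_loadings() if loadings is None else np.asarray(loadings, float)
    rng = np.random.default_rng(seed)
    p, k = L.shape
    f = rng.normal(size=(n_samples, k))
    e = rng.normal(scale=noise_sd, size=(n_samples, p))
    return f @ L.T + e, f
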