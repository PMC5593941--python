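"""Shared principal-component helper with a deterministic sign rule."""

from __future__ import annotations

import numpy as np


def principal_components(values: np.ndarray, n_components: int = 2):
    """PCA of a genes × samples matrix, samples as observations.

    Each gene (variable) is mean-centred; components come from the SVD of
    the centred matrix.  The sign of every component is fixed so that the
    sum of its gene loadings is >= 0, removing the SVD sign ambiguity.

    Returns
    -------
    scores : (n_samples, k) array of PC scores per sample
    loadings : (n_genes, k) array of gene loadings
    explained_var : (k,) sample variances of the scores (ddof=1)
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D genes × samples matrix")
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.isnan(values).any():
        raise ValueError("PCA input must be complete (no missing values)")
    centred = values - values.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, len(s))
    loadings = u[:, :k]
    scores = (s[:k, None] * vt[:k, :]).T
    flip = loadings.sum(axis=0) < 0
    loadings[:, flip] *= -1.0
    scores[:, flip] *= -1.0
    explained_var = s[:k] ** 2 / (n_samples - 1)
    return scores, loadings, explained_var
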