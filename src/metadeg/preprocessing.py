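"""Missing-gene filtering, k-NN imputation and cyclic-loess normalisation.

The preprocessing chain mirrors standard practice for log2-scale expression
matrices: genes missing in more than half of any subgroup are dropped,
remaining gaps are filled by gene-wise k-nearest-neighbour imputation, and
between-sample intensity trends are removed by pairwise cyclic loess on
MA coordinates.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._pca import principal_components

logger = logging.getLogger(__name__)


def _check_expression(expr: pd.DataFrame) -> None:
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers")


def filter_missing_genes(expr: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Drop genes missing in more than half of any subgroup's samples.

    A gene is removed iff, within at least one group label, its number of
    missing entries strictly exceeds half that subgroup's size ("more than
    half"); surviving genes keep their input order.
    """
    _check_expression(expr)
    groups = ann.loc[expr.columns, "group"]
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    drop = np.zeros(expr.shape[0], dtype=bool)
    for g, cols in groups.groupby(groups).groups.items():
        sub = expr[list(cols)]
        n_missing = sub.isna().sum(axis=1).to_numpy()
        drop |= n_missing > len(cols) / 2.0
    kept = expr.loc[~drop]
    if drop.any():
        logger.info("filter_missing_genes removed %d of %d genes", int(drop.sum()), len(drop))
    return kept


def impute_knn(expr: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Gene-wise k-nearest-neighbour imputation.

    Each missing entry (gene g, sample s) is replaced by the mean of s's
    values over the k genes nearest to g, where distance is the root mean
    squared difference over commonly observed samples.  Candidate
    neighbours must be observed in sample s and share at least one
    observed sample with g; distance ties break by gene order.  Observed
    entries are returned bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_expression(expr)
    values = expr.to_numpy(dtype=float)
    missing = np.isnan(values)
    if not missing.any():
        return expr.copy()
    if missing.all(axis=1).any():
        bad = expr.index[missing.all(axis=1)][:5].tolist()
        raise ValueError(f"genes with all entries missing (filter first): {bad}")

    obs = ~missing
    filled = np.where(missing, 0.0, values)
    rows_with_missing = np.where(missing.any(axis=1))[0]

    # pairwise mean-squared differences over commonly observed entries,
    # computed blockwise between genes-with-gaps and all genes
    out = values.copy()
    n_genes = values.shape[0]
    obs_f = obs.astype(float)
    for start in range(0, len(rows_with_missing), 512):
        block = rows_with_missing[start : start + 512]
        a = filled[block]  # (B, S)
        oa = obs_f[block]
        # common counts and sum of squared diffs over common entries
        common = oa @ obs_f.T  # (B, G)
        cross = a @ filled.T
        sq_a = (a**2) @ obs_f.T
        sq_b = oa @ (filled**2).T
        ssd = sq_a - 2.0 * cross + sq_b
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.maximum(ssd, 0.0) / common)
        dist[common == 0] = np.inf
        for bi, gi in enumerate(block):
            dist[bi, gi] = np.inf  # a gene is not its own neighbour
            order = np.argsort(dist[bi], kind="stable")
            for s in np.where(missing[gi])[0]:
                cand = order[obs[order, s] & np.isfinite(dist[bi, order])]
                if cand.size == 0:
                    # no informative neighbour observed in this sample
                    out[gi, s] = np.nanmean(values[gi])
                    logger.warning(
                        "impute_knn: no neighbour for gene %s sample %s; used gene mean",
                        expr.index[gi],
                        expr.columns[s],
                    )
                    continue
                out[gi, s] = values[cand[:k], s].mean()
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def cyclic_loess_normalize(
    expr: pd.DataFrame, span: float = 0.7, iterations: int = 3
) -> pd.DataFrame:
    """Pairwise cyclic loess normalisation of a complete log2 matrix.

    For each unordered sample pair (i, j) in lexicographic column-position
    order, a degree-1 loess curve of M = x_i − x_j against
    A = (x_i + x_j) / 2 is fitted and the fitted trend is split
    symmetrically: half subtracted from sample i, half added to sample j.
    The full pass over all pairs repeats ``iterations`` times.
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    _check_expression(expr)
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    values = expr.to_numpy(dtype=float).copy()
    if np.isnan(values).any():
        raise ValueError("cyclic loess needs a complete matrix; impute first")

    n = values.shape[1]
    for _ in range(iterations):
        for i, j in combinations(range(n), 2):
            xi, xj = values[:, i], values[:, j]
            a = 0.5 * (xi + xj)
            m = xi - xj
            delta = 0.05 * (a.max() - a.min())
            trend = lowess(m, a, frac=span, it=3, delta=delta, return_sorted=False)
            half = 0.5 * trend
            values[:, i] = xi - half
            values[:, j] = xj + half
    return pd.DataFrame(values, index=expr.index, columns=expr.columns)


def pairwise_ma_trend(expr: pd.DataFrame, span: float = 0.7) -> float:
    """Mean absolute fitted MA trend over all sample pairs (diagnostic)."""
    values = expr.to_numpy(dtype=float)
    total, n_pairs = 0.0, 0
    for i, j in combinations(range(values.shape[1]), 2):
        a = 0.5 * (values[:, i] + values[:, j])
        m = values[:, i] - values[:, j]
        delta = 0.05 * (a.max() - a.min())
        trend = lowess(m, a, frac=span, it=3, delta=delta, return_sorted=False)
        total += float(np.mean(np.abs(trend)))
        n_pairs += 1
    return total / n_pairs


def pca_overview(expr: pd.DataFrame, top_fraction: float = 0.25) -> pd.DataFrame:
    """First two PC scores per sample from the most variable genes.

    Selects ``ceil(top_fraction × n_genes)`` genes by descending standard
    deviation, centres each gene, and returns per-sample scores on the
    first two principal components.
    """
    _check_expression(expr)
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("PCA needs a complete matrix")
    n_top = math.ceil(top_fraction * expr.shape[0])
    sds = values.std(axis=1, ddof=1)
    order = np.argsort(-sds, kind="stable")[:n_top]
    scores, _, _ = principal_components(values[np.sort(order)], n_components=2)
    cols = ["PC1", "PC2"][: scores.shape[1]]
    return pd.DataFrame(scores[:, : len(cols)], index=expr.columns, columns=cols)
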