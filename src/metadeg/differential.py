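"""Per-gene expression differentiation for a stage transition.

The central statistic is the differential score

    D_i = log2(FC_i) * (-log10(P_i))

which combines the log2 fold change of gene i between the two groups of a
transition with the two-sided Wilcoxon p-value (signed-rank for paired
designs, rank-sum otherwise).  The sign of D is carried entirely by the
fold change; the p-value term is nonnegative.  A classical t-test +
Benjamini–Hochberg FDR baseline is provided alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # numeric safety: below any attainable p at study sizes
EXACT_MAX_TOTAL = 25  # exact null enumeration up to this many observations


@dataclass(frozen=True)
class TransitionSpec:
    """An ordered pair of sample groups representing a carcinogenic step."""

    from_group: str
    to_group: str
    paired: bool = False

    def __post_init__(self):
        if self.from_group == self.to_group:
            raise ValueError("transition endpoints must differ")

    def reversed(self) -> "TransitionSpec":
        return TransitionSpec(self.to_group, self.from_group, self.paired)

    @property
    def label(self) -> str:
        return f"{self.from_group}-{self.to_group}"


def _group_matrices(expr: pd.DataFrame, ann: pd.DataFrame, t: TransitionSpec):
    """Split the matrix into (from, to) sample blocks; paired designs are
    matched column-for-column through pair_id."""
    groups = ann.loc[expr.columns, "group"]
    from_cols = expr.columns[groups == t.from_group]
    to_cols = expr.columns[groups == t.to_group]
    if len(from_cols) == 0 or len(to_cols) == 0:
        raise ValueError(
            f"transition {t.label}: empty group "
            f"({t.from_group}: {len(from_cols)}, {t.to_group}: {len(to_cols)})"
        )
    if not t.paired:
        return expr[from_cols], expr[to_cols]
    pairs = ann.loc[list(from_cols) + list(to_cols), "pair_id"]
    from_by_pair = {pairs[c]: c for c in from_cols if pd.notna(pairs[c])}
    to_by_pair = {pairs[c]: c for c in to_cols if pd.notna(pairs[c])}
    shared = sorted(set(from_by_pair) & set(to_by_pair))
    if not shared:
        raise ValueError(f"transition {t.label}: no complete pairs")
    return (
        expr[[from_by_pair[p] for p in shared]],
        expr[[to_by_pair[p] for p in shared]],
    )


def log2_fold_change(
    expr: pd.DataFrame, ann: pd.DataFrame, t: TransitionSpec
) -> pd.Series:
    """Mean log2 expression in to_group minus mean in from_group.

    Positive values mean the gene is up in the later stage.  Inputs are
    already log2-scale, so the difference of means is the log2 fold change.
    """
    a, b = _group_matrices(expr, ann, t)
    fc = b.mean(axis=1) - a.mean(axis=1)
    fc.name = "log2_fc"
    return fc


def rank_test(expr: pd.DataFrame, ann: pd.DataFrame, t: TransitionSpec) -> pd.DataFrame:
    """Two-sided Wilcoxon p per gene: signed-rank if paired, rank-sum otherwise.

    The exact null distribution is used whenever the total observation
    count permits enumeration (<= 25) and the gene has no ties (no zero
    differences in the paired case); otherwise the normal approximation
    with tie/continuity correction.  Genes with all values tied get p = 1
    and a ``degenerate`` warning flag.

    Returns a DataFrame with columns ``p_value`` and ``degenerate``.
    """
    a, b = _group_matrices(expr, ann, t)
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("rank_test needs a complete matrix; impute first")
    n_genes = x.shape[0]
    p = np.ones(n_genes)
    degenerate = np.zeros(n_genes, dtype=bool)

    if t.paired:
        d = y - x
        n = d.shape[1]
        if n < 1:
            raise ValueError("paired test needs at least one pair")
        all_zero = np.all(d == 0, axis=1)
        degenerate |= all_zero
        for i in range(n_genes):
            if all_zero[i]:
                continue
            di = d[i]
            nz = di[di != 0]
            exact_ok = (
                n <= EXACT_MAX_TOTAL
                and nz.size == di.size
                and np.unique(np.abs(nz)).size == nz.size
            )
            method = "exact" if exact_ok else "approx"
            res = stats.wilcoxon(
                di, zero_method="wilcox", correction=(method == "approx"),
                alternative="two-sided", method=method,
            )
            p[i] = res.pvalue
    else:
        n_total = x.shape[1] + y.shape[1]
        if x.shape[1] < 2 or y.shape[1] < 2:
            raise ValueError("unpaired test needs >= 2 samples per group")
        combined = np.concatenate([x, y], axis=1)
        all_tied = np.all(combined == combined[:, :1], axis=1)
        degenerate |= all_tied
        if n_total <= EXACT_MAX_TOTAL:
            for i in range(n_genes):
                if all_tied[i]:
                    continue
                has_ties = np.unique(combined[i]).size < n_total
                method = "asymptotic" if has_ties else "exact"
                res = stats.mannwhitneyu(
                    x[i], y[i], alternative="two-sided", method=method
                )
                p[i] = res.pvalue
        else:
            live = ~all_tied
            if live.any():
                res = stats.mannwhitneyu(
                    x[live], y[live], alternative="two-sided",
                    method="asymptotic", axis=1,
                )
                p[live] = res.pvalue

    if degenerate.any():
        logger.warning("rank_test: %d genes with all values tied (p=1)", int(degenerate.sum()))
    p = np.clip(p, P_FLOOR, 1.0)
    return pd.DataFrame({"p_value": p, "degenerate": degenerate}, index=expr.index)


def differential_score(log2_fc, p):
    """Differential score D = log2_fc × (−log10 p); p must lie in (0, 1]."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("p must be in (0, 1]")
    result = np.asarray(log2_fc, dtype=float) * (-np.log10(p_arr))
    if np.ndim(log2_fc) == 0 and np.ndim(p) == 0:
        return float(result)
    return result


def differential_table(
    expr: pd.DataFrame, ann: pd.DataFrame, t: TransitionSpec
) -> pd.DataFrame:
    """Full per-gene differential result for one transition.

    Columns: ``log2_fc``, ``p_value``, ``d_score``,
    ``direction`` (up / down / null by the sign of log2_fc), ``degenerate``.
    """
    fc = log2_fold_change(expr, ann, t)
    ranks = rank_test(expr, ann, t)
    d = differential_score(fc.to_numpy(), ranks["p_value"].to_numpy())
    direction = np.where(fc > 0, "up", np.where(fc < 0, "down", "null"))
    return pd.DataFrame(
        {
            "log2_fc": fc,
            "p_value": ranks["p_value"],
            "d_score": d,
            "direction": direction,
            "degenerate": ranks["degenerate"],
        },
        index=expr.index,
    )


def t_test_deg(
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    t: TransitionSpec,
    fdr_cut: float = 0.001,
) -> pd.DataFrame:
    """Classical paired / pooled-variance Student t-test with BH-FDR.

    Returns per-gene ``t``, ``p``, ``fdr`` (Benjamini–Hochberg over all
    tested genes) and ``significant`` (fdr < fdr_cut).  Genes constant in
    both groups with zero mean difference get p = 1; constant with a
    nonzero difference get the p floor.
    """
    a, b = _group_matrices(expr, ann, t)
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    if t.paired:
        res = stats.ttest_rel(y, x, axis=1)
        diff = (y - x).mean(axis=1)
    else:
        res = stats.ttest_ind(y, x, axis=1, equal_var=True)
        diff = y.mean(axis=1) - x.mean(axis=1)
    tstat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        zero_diff = np.isclose(diff, 0.0)
        p[bad & zero_diff] = 1.0
        tstat[bad & zero_diff] = 0.0
        p[bad & ~zero_diff] = P_FLOOR
    p = np.clip(p, P_FLOOR, 1.0)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"t": tstat, "p": p, "fdr": fdr, "significant": fdr < fdr_cut},
        index=expr.index,
    )
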