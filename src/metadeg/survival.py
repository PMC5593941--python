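"""Genome-wide univariate Cox screening and top-N average-|coefficient| curves.

Every gene is z-scored and fitted in its own univariate Cox proportional-
hazards model (Breslow handling of tied event times), so absolute
coefficients are comparable across genes and can be averaged.  For a
transition's top-N differential genes the average absolute Cox coefficient
(AACCV) quantifies how survival-relevant that gene list is; AACCV values
of two transitions are compared with a two-sided rank-sum test.

The per-gene fits use an in-package Newton solver on the Breslow partial
likelihood, vectorised over genes, which makes screening thousands of
genes (and simulation replicates of it) cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .significance import select_top_n

logger = logging.getLogger(__name__)

MAX_ABS_COEF = 50.0  # beyond this the fit is treated as diverged


def cox_univariate_batch(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Univariate Cox fits for each row of X against one survival outcome.

    Maximises the Breslow partial likelihood

        l(b) = sum_{i: event} [ b x_i − log sum_{j: t_j >= t_i} exp(b x_j) ]

    by Newton's method, vectorised across genes (rows).  Tied event times
    share the full risk set of their time point (Breslow).  Standard
    errors come from the observed information; p-values are two-sided Wald.

    Returns a DataFrame with columns coef, se, p, converged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = time.size
    if X.shape[1] != n:
        raise ValueError("X columns must match the number of samples")
    if event.sum() < 1:
        raise ValueError("no events in the data")

    order = np.argsort(time, kind="stable")
    Xs = X[:, order]
    ts = time[order]
    ev = event[order].astype(bool)

    # first index of each tie group: risk set of an event at t is every
    # sample from the first occurrence of t onwards
    first_idx = np.zeros(n, dtype=int)
    for i in range(1, n):
        first_idx[i] = first_idx[i - 1] if ts[i] == ts[i - 1] else i
    ev_pos = np.where(ev)[0]
    risk_start = first_idx[ev_pos]  # (E,)
    x_events_sum = Xs[:, ev_pos].sum(axis=1)  # (G,)

    G = Xs.shape[0]
    beta = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    info = np.full(G, np.nan)
    active = np.ones(G, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        b = beta[active, None]
        xa = Xs[active]
        bx = b * xa
        # per-gene rescaling cancels in every ratio below; avoids overflow
        w = np.exp(bx - bx.max(axis=1, keepdims=True))  # (g, n)
        xw = xa * w
        x2w = xa * xw
        # suffix cumulative sums along samples
        s0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1][:, risk_start]
        s1 = np.cumsum(xw[:, ::-1], axis=1)[:, ::-1][:, risk_start]
        s2 = np.cumsum(x2w[:, ::-1], axis=1)[:, ::-1][:, risk_start]
        mean = s1 / s0
        grad = x_events_sum[active] - mean.sum(axis=1)
        hess = (s2 / s0 - mean**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(hess > 0, grad / hess, 0.0)
        step = np.clip(step, -2.0, 2.0)  # guard against overshoot
        new_beta = beta[active] + step
        done = np.abs(step) < tol
        idx = np.where(active)[0]
        beta[idx] = new_beta
        info[idx] = hess
        converged[idx[done]] = True
        diverged = np.abs(new_beta) > MAX_ABS_COEF
        active[idx[done | diverged]] = False

    ok = converged & np.isfinite(info) & (info > 0)
    se = np.where(ok, 1.0 / np.sqrt(np.where(info > 0, info, np.nan)), np.nan)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return pd.DataFrame({"coef": beta, "se": se, "p": p, "converged": ok})


def cox_per_gene(expr: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Univariate Cox screen of every gene over the cancer samples with OS.

    Expression is z-scored per gene (so coefficients are log-hazards per
    SD of expression and comparable across genes).  Constant genes are
    flagged degenerate with coef 0; non-converged fits are flagged and
    excluded from downstream averages.

    Returns a DataFrame indexed by gene with columns coef, hr, se, p,
    n_used, converged, degenerate.
    """
    ann = ann.loc[[s for s in expr.columns if s in ann.index]]
    use = ann[(ann["group"] != "normal") & ann["os_time"].notna() & ann["os_event"].notna()]
    if len(use) == 0:
        raise ValueError("no cancer samples with survival data")
    time = use["os_time"].to_numpy(dtype=float)
    event = use["os_event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for Cox screening")

    values = expr[use.index].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("Cox screen needs a complete matrix; impute first")
    sd = values.std(axis=1, ddof=1)
    degenerate = sd == 0
    z = np.zeros_like(values)
    live = ~degenerate
    z[live] = (values[live] - values[live].mean(axis=1, keepdims=True)) / sd[live, None]

    out = pd.DataFrame(
        {
            "coef": 0.0,
            "hr": 1.0,
            "se": np.nan,
            "p": 1.0,
            "n_used": len(use),
            "converged": False,
            "degenerate": degenerate,
        },
        index=expr.index,
    )
    if live.any():
        fit = cox_univariate_batch(z[live], time, event)
        idx = expr.index[live]
        out.loc[idx, "coef"] = fit["coef"].to_numpy()
        out.loc[idx, "se"] = fit["se"].to_numpy()
        out.loc[idx, "p"] = fit["p"].to_numpy()
        out.loc[idx, "converged"] = fit["converged"].to_numpy()
    out["hr"] = np.exp(out["coef"])
    n_bad = int((~out["converged"] & ~out["degenerate"]).sum())
    if n_bad:
        logger.warning("cox_per_gene: %d genes did not converge", n_bad)
    return out


@dataclass
class AACCVPoint:
    """Average absolute Cox coefficient of a transition's top-N gene list."""

    transition: str
    direction: str
    top_n: int
    aaccv: float
    member_abs_coefs: List[float] = field(default_factory=list)
    n_skipped: int = 0


def aaccv_curve(
    cox: pd.DataFrame,
    diff: pd.DataFrame,
    top_ns: Sequence[int],
    direction: str,
    transition: str = "",
) -> List[AACCVPoint]:
    """AACCV at each requested top-N for one transition and direction.

    Genes are ranked by differential score (``select_top_n``); members
    without a converged, non-degenerate Cox fit are skipped with a logged
    count before averaging |coef|.
    """
    points = []
    for n in top_ns:
        genes = select_top_n(diff, n, direction)
        sub = cox.loc[genes]
        good = sub["converged"] & ~sub["degenerate"]
        n_skipped = int((~good).sum())
        coefs = sub.loc[good, "coef"].abs()
        if len(coefs) == 0:
            raise ValueError(f"no usable Cox fits among top {n} {direction} genes")
        if n_skipped:
            logger.info(
                "aaccv_curve %s %s top %d: skipped %d genes without converged fits",
                transition, direction, n, n_skipped,
            )
        points.append(
            AACCVPoint(
                transition=transition,
                direction=direction,
                top_n=n,
                aaccv=float(coefs.mean()),
                member_abs_coefs=[float(c) for c in coefs],
                n_skipped=n_skipped,
            )
        )
    return points


def combine_bidirectional(up: AACCVPoint, down: AACCVPoint) -> AACCVPoint:
    """Concatenate a transition's up and down member lists (same top-N)."""
    if up.top_n != down.top_n or up.transition != down.transition:
        raise ValueError("can only combine matching top-N points of one transition")
    members = up.member_abs_coefs + down.member_abs_coefs
    return AACCVPoint(
        transition=up.transition,
        direction="both",
        top_n=up.top_n,
        aaccv=float(np.mean(members)),
        member_abs_coefs=members,
        n_skipped=up.n_skipped + down.n_skipped,
    )


def compare_transitions(a: AACCVPoint, b: AACCVPoint) -> Tuple[float, float]:
    """Two-sided rank-sum test of |coef| members between two AACCV points."""
    xa = np.asarray(a.member_abs_coefs, dtype=float)
    xb = np.asarray(b.member_abs_coefs, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("member_abs_coefs must be non-empty in both points")
    combined = np.concatenate([xa, xb])
    if np.all(combined == combined[0]):
        return 0.0, 1.0
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def coef_density_summary(
    cox: pd.DataFrame, gene_sets: Dict[str, Sequence[str]]
) -> Dict[str, dict]:
    """Coefficient vectors and moments per named gene set (for plotting).

    Degenerate / non-converged members are dropped; a set reduced to one
    member reports sd as NaN with a flag.
    """
    out = {}
    for name, genes in gene_sets.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        unknown = [g for g in genes if g not in cox.index]
        if unknown:
            raise KeyError(f"gene set {name!r} has unknown genes: {unknown[:5]}")
        sub = cox.loc[genes]
        coefs = sub.loc[sub["converged"] & ~sub["degenerate"], "coef"].to_numpy()
        out[name] = {
            "coefs": coefs.tolist(),
            "mean": float(np.mean(coefs)) if coefs.size else float("nan"),
            "sd": float(np.std(coefs, ddof=1)) if coefs.size > 1 else float("nan"),
            "sd_undefined": coefs.size < 2,
            "n": int(coefs.size),
        }
    return out
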