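"""Normal fit to differential scores and one-sided tail DEG calling.

Scores are summarised by their sample mean and SD; the Kolmogorov–Smirnov
statistic of the scores against the fitted normal is reported but does not
gate the calling.  A gene is called a significant up- (down-) regulated
DEG when its score falls in the upper (lower) one-sided tail of the fitted
normal at the chosen level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ScoreDistributionFit:
    """Moments fit of a normal to a score vector, with its KS statistic."""

    mu: float
    sigma: float
    ks_D: float
    ks_p: float
    n: int


def fit_score_normal(d_scores) -> ScoreDistributionFit:
    """Fit Normal(mu, sigma) to the scores by moments and report the KS test.

    ``sigma`` uses the n−1 denominator; the KS statistic is the one-sample
    supremum distance of the empirical CDF from the fitted normal, with the
    p-value from the asymptotic KS distribution.
    """
    scores = np.asarray(d_scores, dtype=float)
    if scores.ndim != 1:
        scores = scores.ravel()
    if scores.size < 3:
        raise ValueError("need at least 3 scores to fit")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    mu = float(scores.mean())
    sigma = float(scores.std(ddof=1))
    if sigma == 0:
        raise ValueError("zero variance in scores; normal fit undefined")
    ks = stats.kstest(scores, "norm", args=(mu, sigma), method="asymp")
    return ScoreDistributionFit(mu=mu, sigma=sigma, ks_D=float(ks.statistic), ks_p=float(ks.pvalue), n=scores.size)


def call_degs(d_scores: pd.Series, fit: ScoreDistributionFit, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided normal-tail significance calls for each gene.

    Genes with score >= mu are assessed in the upper tail
    (tail_p = 1 − Φ((D−mu)/σ), direction "up"); scores below mu in the
    lower tail (tail_p = Φ((D−mu)/σ), direction "down").  A gene is
    significant iff tail_p < alpha (strict).
    """
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    scores = pd.Series(d_scores).astype(float)
    z = (scores.to_numpy() - fit.mu) / fit.sigma
    upper = z >= 0
    tail_p = np.where(upper, stats.norm.sf(z), stats.norm.cdf(z))
    direction = np.where(upper, "up", "down")
    return pd.DataFrame(
        {
            "tail_p": tail_p,
            "direction": direction,
            "significant": tail_p < alpha,
        },
        index=scores.index,
    )


def select_top_n(diff: pd.DataFrame, n: int, direction: str) -> list:
    """Top-n gene ids by differential score in one direction.

    ``up``: the n largest positive d_scores, descending; ``down``: the n
    most negative, ascending.  Score ties break by lexicographic gene id.
    Raises if fewer than n genes carry the requested sign.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if n < 0:
        raise ValueError("n must be nonnegative")
    scores = diff["d_score"]
    if direction == "up":
        pool = scores[scores > 0]
        key = pool.to_frame("d").assign(g=pool.index).sort_values(
            ["d", "g"], ascending=[False, True]
        )
    else:
        pool = scores[scores < 0]
        key = pool.to_frame("d").assign(g=pool.index).sort_values(
            ["d", "g"], ascending=[True, True]
        )
    if len(pool) < n:
        raise ValueError(
            f"requested top {n} {direction}-regulated genes but only "
            f"{len(pool)} have {'positive' if direction == 'up' else 'negative'} scores "
            f"(short by {n - len(pool)})"
        )
    return key.index[:n].tolist()
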