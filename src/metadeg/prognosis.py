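"""Prognostic validation of a gene module.

The module's expression is summarised by the first principal component
(PC1) of the gene-centred submatrix; samples are dichotomised at the
median PC1 into high/low groups and compared by Kaplan–Meier / log-rank.
Clinical independence is assessed with a stepwise Cox table: univariate
proportional-hazards fits per factor, then one joint multivariate fit of
the factors passing the univariate screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from ._pca import principal_components

logger = logging.getLogger(__name__)


@dataclass
class PrognosisResult:
    """PC1 summary, median-split groups and two-group survival comparison."""

    pc1: pd.Series
    group: pd.Series
    logrank_chi2: Optional[float] = None
    logrank_p: Optional[float] = None
    km_curves: Dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class CoxTableRow:
    """One factor's row in the univariate / multivariate Cox table."""

    factor: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    stage: str  # "univariate" | "multivariate"
    note: str = ""  # "", "excluded", "degenerate"


def pc1_split(expr: pd.DataFrame, genes: Iterable[str]) -> PrognosisResult:
    """PC1 of the gene submatrix and the median dichotomisation.

    PC1 is computed on the gene-centred submatrix restricted to ``genes``,
    with its sign fixed so the sum of gene loadings is nonnegative.
    Samples with pc1 > median go to "high"; pc1 < median and exact-median
    samples go to "low" (so an odd sample count yields sizes differing
    by one).
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    sub = expr.loc[genes]
    if sub.shape[1] < 2:
        raise ValueError("PC1 split needs at least 2 samples")
    scores, _, _ = principal_components(sub.to_numpy(dtype=float), n_components=1)
    pc1 = pd.Series(scores[:, 0], index=expr.columns, name="pc1")
    med = float(pc1.median())
    group = pd.Series(np.where(pc1 > med, "high", "low"), index=pc1.index, name="group")
    return PrognosisResult(pc1=pc1, group=group)


def km_logrank(ann: pd.DataFrame, group: pd.Series) -> PrognosisResult:
    """Kaplan–Meier curves per group and the two-group log-rank test."""
    samples = group.index.intersection(ann.index)
    group = group.loc[samples]
    sub = ann.loc[samples]
    ok = sub["os_time"].notna() & sub["os_event"].notna()
    sub, group = sub[ok], group[ok]
    labels = sorted(group.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    curves = {}
    for lab in labels:
        members = group[group == lab].index
        if len(members) == 0:
            raise ValueError(f"group {lab!r} has no samples")
        events = sub.loc[members, "os_event"]
        if events.sum() < 1:
            raise ValueError(f"group {lab!r} has no events")
        km = KaplanMeierFitter()
        km.fit(sub.loc[members, "os_time"], events, label=lab)
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[lab] = sf
    a, b = labels
    ga = group[group == a].index
    gb = group[group == b].index
    res = logrank_test(
        sub.loc[ga, "os_time"], sub.loc[gb, "os_time"],
        event_observed_A=sub.loc[ga, "os_event"],
        event_observed_B=sub.loc[gb, "os_event"],
    )
    return PrognosisResult(
        pc1=pd.Series(dtype=float),
        group=group,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        km_curves=curves,
    )


def _encode_factor(name: str, values: pd.Series) -> pd.Series:
    """Numeric coding matching the usual clinical contrasts.

    age: continuous; sex: male vs female indicator; stage: later-stage vs
    the lowest observed label; any other factor must already be numeric or
    binary high/low.
    """
    if name == "age":
        return values.astype(float)
    if name == "sex":
        return (values.astype(str).str.lower() == "male").astype(float)
    if name == "stage":
        ref = min(values.dropna().astype(str))
        return (values.astype(str) != ref).astype(float)
    if values.dtype == object:
        uniq = sorted(values.dropna().unique())
        if set(uniq) <= {"high", "low"}:
            return (values == "high").astype(float)
        raise ValueError(f"cannot encode factor {name!r} with levels {uniq}")
    return values.astype(float)


def stepwise_cox(
    ann: pd.DataFrame,
    group: pd.Series,
    covariates: Sequence[str] = ("age", "sex", "stage"),
    alpha_enter: float = 0.05,
    pc1: Optional[pd.Series] = None,
    pc1_continuous: bool = False,
) -> List[CoxTableRow]:
    """Univariate screening then one joint multivariate Cox fit.

    Factors are the clinical covariates plus the module signature — the
    binary PC1 median-split group by default, or the continuous PC1 when
    ``pc1_continuous`` (then ``pc1`` must be supplied).  Samples missing
    any factor or survival field are dropped listwise.  Factors with
    univariate p < ``alpha_enter`` enter the multivariate fit; the rest
    carry an "excluded" note.  Constant factors are flagged degenerate and
    never enter.
    """
    samples = group.index.intersection(ann.index)
    df = ann.loc[samples, list(covariates) + ["os_time", "os_event"]].copy()
    if pc1_continuous:
        if pc1 is None:
            raise ValueError("continuous PC1 requested but no pc1 values supplied")
        df["PC1"] = pc1.loc[samples].astype(float)
    else:
        df["PC1"] = group.loc[samples].astype(str)
    df = df.dropna()
    if len(df) == 0:
        raise ValueError("no samples with complete factor and survival data")

    factors = list(covariates) + ["PC1"]
    encoded = pd.DataFrame(index=df.index)
    for f in factors:
        encoded[f] = _encode_factor(f, df[f])
    encoded["os_time"] = df["os_time"].astype(float)
    encoded["os_event"] = df["os_event"].astype(int)

    rows: List[CoxTableRow] = []
    uni_p: Dict[str, float] = {}
    for f in factors:
        if encoded[f].nunique() < 2:
            rows.append(
                CoxTableRow(f, float("nan"), float("nan"), float("nan"), float("nan"),
                            "univariate", note="degenerate")
            )
            logger.warning("stepwise_cox: factor %s is constant; skipped", f)
            continue
        cph = CoxPHFitter()
        cph.fit(encoded[[f, "os_time", "os_event"]], "os_time", "os_event")
        s = cph.summary.loc[f]
        rows.append(
            CoxTableRow(
                f,
                float(s["exp(coef)"]),
                float(s["exp(coef) lower 95%"]),
                float(s["exp(coef) upper 95%"]),
                float(s["p"]),
                "univariate",
            )
        )
        uni_p[f] = float(s["p"])

    entered = [f for f in factors if f in uni_p and uni_p[f] < alpha_enter]
    if entered:
        cph = CoxPHFitter()
        cph.fit(encoded[entered + ["os_time", "os_event"]], "os_time", "os_event")
        for f in entered:
            s = cph.summary.loc[f]
            rows.append(
                CoxTableRow(
                    f,
                    float(s["exp(coef)"]),
                    float(s["exp(coef) lower 95%"]),
                    float(s["exp(coef) upper 95%"]),
                    float(s["p"]),
                    "multivariate",
                )
            )
    else:
        logger.warning("stepwise_cox: no factor passed univariate screening")
    for f in factors:
        if f in uni_p and f not in entered:
            rows.append(
                CoxTableRow(f, float("nan"), float("nan"), float("nan"), float("nan"),
                            "multivariate", note="excluded")
            )
    return rows
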