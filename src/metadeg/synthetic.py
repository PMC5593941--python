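"""Synthetic cohorts with planted differential genes, survival and network module.

The generator emulates the three inputs of the analysis — a log2-scale
expression matrix over staged tumour groups, a clinical annotation table
with overall survival, and an undirected gene-interaction network — with
the statistical structure the pipeline assumes:

* gene-wise Gaussian expression on the log2 scale, with planted up/down
  shifts in the later group of one configured transition and a shared
  subject effect for paired normal/tumour samples;
* exponential proportional-hazards survival whose log-hazard is
  ``surv_beta`` times the standardised PC1 of a signature gene set, with
  independent uniform censoring calibrated to a target censoring fraction;
* an Erdős–Rényi-style random simple graph into which the planted module
  genes are wired as one connected subgraph, kept free of edges to planted
  DEGs outside the module so the module is recoverable by construction.

All randomness derives from ``SimulationConfig.seed`` through one
independent stream per output object (expression / survival / network), so
enlarging the gene panel does not perturb the survival draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._pca import principal_components
from .config import GROUPS, SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for a simulated cohort."""

    planted_up: Set[str] = field(default_factory=set)
    planted_down: Set[str] = field(default_factory=set)
    planted_module: Set[str] = field(default_factory=set)
    per_sample_linear_predictor: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.planted_up & self.planted_down:
            raise ValueError("planted_up and planted_down overlap")
        if not self.planted_module <= (self.planted_up | self.planted_down):
            raise ValueError("planted_module must be a subset of the planted DEGs")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # One independent stream per output object, all derived from the master
    # seed; stream 0 = expression, 1 = survival, 2 = network.
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def gene_ids(n_genes: int):
    return [f"G{i:05d}" for i in range(n_genes)]


def simulate_expression(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate (expression, annotation, truth) for a staged cohort.

    Planted up-genes are shifted by ``+effect_size`` log2 units in the later
    group of ``config.transition``; down-genes by ``-effect_size``.  Each
    normal sample is paired with a confined tumour sample through a shared
    subject effect of SD ``pairing_sd``.  ``missing_rate`` of entries are
    replaced by NaN.
    """
    config.validate()
    rng = _rng(config, 0)

    genes = gene_ids(config.n_genes)
    groups = [g for g in GROUPS if config.group_sizes.get(g, 0) > 0]
    sample_ids, sample_groups = [], []
    for g in groups:
        n = int(config.group_sizes[g])
        sample_ids += [f"{g}_{i:03d}" for i in range(n)]
        sample_groups += [g] * n
    if not sample_ids:
        raise ValueError("no samples configured")
    n_samples = len(sample_ids)
    group_arr = np.array(sample_groups)

    # planted DEGs: a seed-determined draw without replacement
    n_planted = config.n_deg_up + config.n_deg_down
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    up_idx = planted_idx[: config.n_deg_up]
    down_idx = planted_idx[config.n_deg_up :]

    values = config.baseline_mean + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))

    to_group = config.transition[1]
    to_mask = group_arr == to_group
    if to_mask.any():
        values[np.ix_(up_idx, np.where(to_mask)[0])] += config.effect_size
        values[np.ix_(down_idx, np.where(to_mask)[0])] -= config.effect_size

    # paired normal / confined subject effects
    n_normal = int(config.group_sizes.get("normal", 0))
    pair_id = pd.Series([pd.NA] * n_samples, index=sample_ids, dtype="object")
    if n_normal > 0:
        normal_cols = np.where(group_arr == "normal")[0]
        confined_cols = np.where(group_arr == "confined")[0][:n_normal]
        effects = rng.normal(0.0, config.pairing_sd, size=n_normal)
        for j, (cn, cc) in enumerate(zip(normal_cols, confined_cols)):
            values[:, cn] += effects[j]
            values[:, cc] += effects[j]
            pid = f"P{j:03d}"
            pair_id.iloc[cn] = pid
            pair_id.iloc[cc] = pid

    if config.missing_rate > 0:
        mask = rng.random(size=values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = np.nan

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)

    age = np.clip(np.round(rng.normal(65.0, 10.0, size=n_samples)), 30, 90)
    sex = np.where(rng.random(n_samples) < 0.55, "male", "female")
    stage_by_group = {
        "confined": ("I", "II"),
        "lymphnode": ("II", "III"),
        "metastasis": ("IV", "IV"),
    }
    stage = []
    for g in sample_groups:
        if g == "normal":
            stage.append(pd.NA)
        else:
            opts = stage_by_group[g]
            stage.append(opts[int(rng.integers(0, 2))])
    ann = pd.DataFrame(
        {
            "group": sample_groups,
            "pair_id": pair_id.values,
            "os_time": np.nan,
            "os_event": np.nan,
            "age": age,
            "sex": sex,
            "stage": stage,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = SyntheticTruth(
        planted_up={genes[i] for i in up_idx},
        planted_down={genes[i] for i in down_idx},
    )
    if config.planted_module_size > 0:
        ordered = sorted(truth.planted_up | truth.planted_down)
        module = rng.choice(len(ordered), size=config.planted_module_size, replace=False)
        truth.planted_module = {ordered[i] for i in module}
    truth.validate()
    return expr, ann, truth


def _calibrate_censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Upper bound of the uniform censoring window hitting censor_rate in expectation.

    For C ~ U(0, c) and T ~ Exp(rate λ), P(censored) = (1 − e^{−λc}) / (λc);
    the mean over samples is monotone decreasing in c, so solve by bisection.
    """

    def mean_censored(c):
        x = rates * c
        return float(np.mean(-np.expm1(-x) / x))

    lo, hi = 1e-9 / rates.max(), 1.0 / rates.min()
    while mean_censored(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12 / rates.min():  # pragma: no cover - pathological rates
            break
    return brentq(lambda c: mean_censored(c) - censor_rate, lo, hi, xtol=1e-12, rtol=1e-12)


def simulate_survival(
    ann: pd.DataFrame,
    expr: pd.DataFrame,
    signature: Iterable[str],
    config: SimulationConfig,
    truth: Optional[SyntheticTruth] = None,
) -> pd.DataFrame:
    """Attach proportional-hazards survival to the annotation table.

    Event times are exponential with rate
    ``baseline_hazard * exp(surv_beta * z)``, where ``z`` is the
    standardised first principal component of the signature submatrix.
    Independent uniform censoring on ``(0, c_max)`` is calibrated so the
    expected censored fraction equals ``censor_rate``.
    """
    signature = sorted(set(signature))
    if not signature:
        raise ValueError("signature must be non-empty")
    missing = [g for g in signature if g not in expr.index]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing[:5]}")
    config.validate()
    rng = _rng(config, 1)

    sub = expr.loc[signature, ann.index].to_numpy(dtype=float)
    # missing entries do not carry signal; fill with the gene mean
    if np.isnan(sub).any():
        row_mean = np.nanmean(sub, axis=1, keepdims=True)
        sub = np.where(np.isnan(sub), row_mean, sub)
    scores, _, _ = principal_components(sub, n_components=1)
    pc1 = scores[:, 0]
    sd = pc1.std(ddof=1)
    z = (pc1 - pc1.mean()) / sd if sd > 0 else np.zeros_like(pc1)
    lp = config.surv_beta * z

    rates = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / rates)
    if config.censor_rate > 0:
        c_max = _calibrate_censor_horizon(rates, config.censor_rate)
        censor_time = rng.uniform(0.0, c_max, size=len(event_time))
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time = event_time
        event = np.ones(len(event_time), dtype=int)

    out = ann.copy()
    out["os_time"] = time
    out["os_event"] = event
    if truth is not None:
        truth.per_sample_linear_predictor = dict(zip(ann.index, map(float, lp)))
    return out


def simulate_network(config: SimulationConfig, truth: SyntheticTruth) -> nx.Graph:
    """Random simple graph with the planted module wired as one connected subgraph.

    Module genes form a random spanning tree (guaranteeing connectivity);
    remaining edges are sampled uniformly among pairs that do not connect
    two planted DEGs outside the module, so projecting the planted DEG set
    onto the network recovers the module as the biggest component.
    """
    config.validate()
    truth.validate()
    rng = _rng(config, 2)

    module = sorted(truth.planted_module)
    planted = sorted(truth.planted_up | truth.planted_down)
    n_nodes = int(config.network_n_nodes)
    if len(planted) > n_nodes:
        raise ValueError("network_n_nodes smaller than the planted DEG count")

    # node labels: all planted DEGs, then other gene ids, then fillers
    all_genes = gene_ids(config.n_genes)
    others = [g for g in all_genes if g not in set(planted)]
    nodes = list(planted)
    need = n_nodes - len(nodes)
    if need > 0:
        take = min(need, len(others))
        pick = rng.choice(len(others), size=take, replace=False)
        nodes += [others[i] for i in sorted(pick)]
        for i in range(need - take):
            nodes.append(f"X{i:05d}")
    nodes = sorted(nodes)
    index = {v: i for i, v in enumerate(nodes)}

    planted_set = set(planted)
    module_set = set(module)

    def allowed(u: str, v: str) -> bool:
        both_deg = u in planted_set and v in planted_set
        both_mod = u in module_set and v in module_set
        return (not both_deg) or both_mod

    edges = set()
    # random spanning tree over the module (random attachment order)
    if len(module) >= 2:
        order = [module[i] for i in rng.permutation(len(module))]
        for i in range(1, len(order)):
            j = int(rng.integers(0, i))
            u, v = sorted((order[i], order[j]))
            edges.add((u, v))

    n_total = int(config.network_n_edges)
    n_pairs = n_nodes * (n_nodes - 1) // 2
    d = len(planted_set & set(nodes))
    m = len(module_set)
    disallowed = d * (d - 1) // 2 - m * (m - 1) // 2
    max_edges = n_pairs - disallowed
    if n_total > max_edges:
        raise ValueError(
            f"network_n_edges={n_total} exceeds the simple-graph maximum "
            f"of {max_edges} under the module wiring constraints"
        )
    if len(edges) > n_total:
        raise ValueError(
            "network_n_edges smaller than the spanning tree of the planted module"
        )

    # uniform sampling of the remaining edges; rejection is cheap while the
    # graph stays sparse, with an enumeration fallback for dense requests
    remaining = n_total - len(edges)
    if remaining > 0 and remaining > 0.25 * max_edges:
        pool = [
            (nodes[i], nodes[j])
            for i in range(n_nodes)
            for j in range(i + 1, n_nodes)
            if allowed(nodes[i], nodes[j]) and (nodes[i], nodes[j]) not in edges
        ]
        pick = rng.choice(len(pool), size=remaining, replace=False)
        edges.update(pool[i] for i in pick)
    else:
        while remaining > 0:
            i, j = rng.integers(0, n_nodes, size=2)
            if i == j:
                continue
            u, v = sorted((nodes[int(i)], nodes[int(j)]))
            if not allowed(u, v) or (u, v) in edges:
                continue
            edges.add((u, v))
            remaining -= 1

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(sorted(edges))
    return g


def simulate_all(config: SimulationConfig):
    """Full synthetic bundle: (expression, annotation, truth, network).

    Survival is tied to the planted module genes (falling back to all
    planted DEGs if no module is configured).
    """
    expr, ann, truth = simulate_expression(config)
    signature = truth.planted_module or (truth.planted_up | truth.planted_down)
    if not signature:  # null simulation: hazard ties to an arbitrary panel
        signature = set(gene_ids(config.n_genes)[: min(20, config.n_genes)])
    ann = simulate_survival(ann, expr, signature, config, truth)
    net = simulate_network(config, truth)
    return expr, ann, truth, net
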