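"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence, Optional

GROUPS = ("normal", "confined", "lymphnode", "metastasis")
CANCER_GROUPS = ("confined", "lymphnode", "metastasis")


def _default_group_sizes() -> dict:
    # A desk-scale rendition of a staged cohort: paired adjacent-normal
    # tissue plus three primary-tumour groups of decreasing size, mirroring
    # the strong confined > lymphnode > metastasis imbalance of real cohorts.
    return {"normal": 15, "confined": 30, "lymphnode": 22, "metastasis": 10}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Expression is simulated directly on the log2 scale as
    ``baseline_mean + group shift + subject effect + N(0, noise_sd)``;
    the pipeline consumes log2-normalised values, so simulating
    post-normalisation values isolates the statistics under test.

    Attributes
    ----------
    n_genes:
        Number of genes (rows) in the expression matrix.
    group_sizes:
        Samples per group label; keys drawn from
        ``{"normal", "confined", "lymphnode", "metastasis"}``.
    n_deg_up, n_deg_down:
        Planted differentially expressed genes for the configured
        transition, shifted by ``+effect_size`` / ``-effect_size`` log2
        units in the transition's later group.
    effect_size:
        Planted shift in log2 units.
    noise_sd:
        Residual per-entry standard deviation, log2 units.
    baseline_mean:
        Grand mean expression, log2 units.
    pairing_sd:
        SD of the shared subject effect linking each normal sample to its
        paired tumour sample, log2 units.
    surv_beta:
        Log-hazard per unit of the standardised PC1 of the survival
        signature gene set.
    baseline_hazard:
        Exponential baseline event rate (events per time unit; days).
    censor_rate:
        Expected fraction of samples censored under independent uniform
        censoring.
    missing_rate:
        Fraction of expression entries replaced by missing markers.
    network_n_nodes, network_n_edges:
        Size of the simulated interaction network.
    planted_module_size:
        Number of planted DEGs wired into one connected network module.
    transition:
        (from_group, to_group) pair whose later group carries the planted
        expression shifts.
    seed:
        Master seed; every output object draws from its own stream derived
        from it.
    """

    n_genes: int = 1200
    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    n_deg_up: int = 60
    n_deg_down: int = 60
    effect_size: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    pairing_sd: float = 0.5
    surv_beta: float = 0.5
    baseline_hazard: float = 1.0 / 1000.0
    censor_rate: float = 0.4
    missing_rate: float = 0.01
    network_n_nodes: int = 400
    network_n_edges: int = 1600
    planted_module_size: int = 20
    transition: tuple = ("confined", "lymphnode")
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_deg_up": self.n_deg_up,
            "n_deg_down": self.n_deg_down,
            "network_n_nodes": self.network_n_nodes,
            "network_n_edges": self.network_n_edges,
            "planted_module_size": self.planted_module_size,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if int(n) != n or n < 0:
                raise ValueError(f"group size for {g!r} must be a nonnegative integer")
        if self.n_deg_up + self.n_deg_down > self.n_genes:
            raise ValueError("planted DEG counts exceed n_genes")
        if self.planted_module_size > self.n_deg_up + self.n_deg_down:
            raise ValueError("planted_module_size exceeds number of planted DEGs")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.pairing_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        frm, to = self.transition
        if frm == to:
            raise ValueError("transition endpoints must differ")
        for g in (frm, to):
            if g not in GROUPS:
                raise ValueError(f"unknown transition group {g!r}")
        n_normal = self.group_sizes.get("normal", 0)
        n_confined = self.group_sizes.get("confined", 0)
        if n_normal > 0 and n_confined < n_normal:
            raise ValueError(
                "each normal sample is paired with a confined tumour sample; "
                "need group_sizes['confined'] >= group_sizes['normal']"
            )
        if self.planted_module_size > self.network_n_nodes:
            raise ValueError("planted_module_size exceeds network_n_nodes")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = dict(self.group_sizes)
        d["transition"] = list(self.transition)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "transition" in d:
            d["transition"] = tuple(d["transition"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one of (``expression_path`` + ``annotation_path``) or
    ``simulation`` must be provided.  ``network_paths`` may accompany real
    inputs; with a simulation the network is generated.
    """

    expression_path: Optional[str] = None
    annotation_path: Optional[str] = None
    network_paths: Sequence[str] = ()
    simulation: Optional[SimulationConfig] = None
    transitions: Sequence[tuple] = (
        ("normal", "confined", True),
        ("confined", "lymphnode", False),
        ("lymphnode", "metastasis", False),
    )
    module_transition: tuple = ("confined", "lymphnode")
    top_ns: Sequence[int] = (200, 150, 100, 50)
    alpha: float = 0.05
    knn_k: int = 10
    loess_span: float = 0.7
    loess_iterations: int = 3
    alpha_enter: float = 0.05
    out_dir: str = "metadeg_out"
    seed: int = 0

    def validate(self) -> None:
        has_real = self.expression_path is not None and self.annotation_path is not None
        if not has_real and self.simulation is None:
            raise ValueError(
                "PipelineConfig needs either expression+annotation paths or a simulation"
            )
        if not (0 < self.alpha < 0.5):
            raise ValueError("alpha must be in (0, 0.5)")
        if not (0 < self.loess_span <= 1):
            raise ValueError("loess_span must be in (0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not self.top_ns:
            raise ValueError("top_ns must be non-empty")
        if self.simulation is not None:
            self.simulation.validate()

    def to_dict(self) -> dict:
        return {
            "expression_path": self.expression_path,
            "annotation_path": self.annotation_path,
            "network_paths": list(self.network_paths),
            "simulation": None if self.simulation is None else self.simulation.to_dict(),
            "transitions": [list(t) for t in self.transitions],
            "module_transition": list(self.module_transition),
            "top_ns": list(self.top_ns),
            "alpha": self.alpha,
            "knn_k": self.knn_k,
            "loess_span": self.loess_span,
            "loess_iterations": self.loess_iterations,
            "alpha_enter": self.alpha_enter,
            "out_dir": self.out_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "transitions" in d:
            d["transitions"] = [tuple(t) for t in d["transitions"]]
        if "module_transition" in d:
            d["module_transition"] = tuple(d["module_transition"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
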